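"""Morphing engine: interpolation, propagation, frames, invariances."""

import numpy as np
import pytest

from conftest import random_morph_pair
from skinmorph.morph import (
    MorphConfig,
    ReprojectionNeeded,
    build_intermediate_structure,
    generate_morph,
    interpolate_ball_set,
    interpolate_mixed_cell,
    propagate_point,
    scratch_center_weight,
)
from skinmorph.superimposition import superimpose
from skinmorph.wp_algebra import BallSet, WeightedPoint, wp_interpolate


def test_morph_config_validation():
    cfg = MorphConfig(frame_count=5)
    assert cfg.t_schedule[0] == 0.0 and cfg.t_schedule[-1] == 1.0
    with pytest.raises(ValueError):
        MorphConfig(t_schedule=[0.0, 0.5, 0.4, 1.0])
    with pytest.raises(ValueError):
        MorphConfig(t_schedule=[0.1, 0.5, 1.0])
    with pytest.raises(ValueError):
        MorphConfig(frame_count=1)


def test_interpolated_set_cardinality_and_limits():
    src = BallSet([[0, 0, 0], [2, 0, 0]], [2.0, 2.0])
    tgt = BallSet([[0, 1, 0], [1, 1, 0], [2, 1, 0]], [1.5, 1.5, 1.5])
    bt = interpolate_ball_set(src, tgt, 0.5)
    assert len(bt) == 6                          # m x n many-to-many
    eps = interpolate_ball_set(src, tgt, 1e-9)
    for k, (i, j) in enumerate((i, j) for i in range(2) for j in range(3)):
        assert np.allclose(eps.centers[k], src.centers[i], atol=1e-6)
        assert eps.weights[k] == pytest.approx(src.weights[i], abs=1e-6)


def test_pruning_preserves_the_skin():
    """Dropping interpolated balls with empty power cells at t = 0.5 does
    not change the skin mesh (they are redundant for the diagram)."""
    from skinmorph.morph import _static_mesh
    from skinmorph.skin_surface import mesh_hausdorff

    src, tgt = random_morph_pair(21, 2, 3)
    full = interpolate_ball_set(src, tgt, 0.5, prune=False)
    pruned = interpolate_ball_set(src, tgt, 0.5, prune=True)
    assert len(pruned) <= len(full)
    m_full, _ = _static_mesh(full, 0.25, 7, 0.5)
    m_pruned, _ = _static_mesh(pruned, 0.25, 7, 0.5)
    assert mesh_hausdorff(m_full, m_pruned) < 0.25


def test_interpolate_mixed_cell_closed_form():
    rep = WeightedPoint(np.array([0.5, 0, 0]), 2.0)
    z, w = interpolate_mixed_cell(np.zeros(3), np.array([2.0, 0, 0]), 0.25, rep)
    assert np.allclose(z, [0.5, 0, 0])
    assert w == pytest.approx(2.0)               # rep sits on the centre
    z0, w0 = interpolate_mixed_cell(np.zeros(3), np.array([2.0, 0, 0]), 0.0, rep)
    assert np.allclose(z0, 0.0) and w0 == pytest.approx(2.0 - 0.25)


def test_propagate_point_closed_form():
    p = propagate_point(np.array([0.0, 0, 1]), np.zeros(3), 1.0, np.array([1.0, 0, 0]), 4.0)
    assert np.allclose(p, [1.0, 0, 2.0])         # scale factor sqrt(4/1) = 2
    q = propagate_point(np.array([0.3, -0.2, 1]), np.zeros(3), 2.0, np.zeros(3), 2.0)
    assert np.allclose(q, [0.3, -0.2, 1])        # identity when nothing moves
    with pytest.raises(ReprojectionNeeded):
        propagate_point(np.zeros(3), np.zeros(3), 1.0, np.zeros(3), -1.0)
    with pytest.raises(ReprojectionNeeded):
        propagate_point(np.zeros(3), np.zeros(3), 1e-12, np.zeros(3), 1.0)


def test_center_linearity_matches_scratch_oracle():
    """The linear-in-t centre model reproduces from-scratch equal-power
    solves on B(t) to high precision (the framework's key equivalence)."""
    src, tgt = random_morph_pair(7, 3, 3)
    struct = build_intermediate_structure(src, tgt, seed=0)
    for tc in struct.tracked:
        for t in (0.25, 0.5, 0.75):
            z_lin = tc.center_at(t)
            w_lin = tc.weight_at(t, src, tgt)
            z_sc, w_sc = scratch_center_weight(src, tgt, tc.pairs, t)
            assert np.linalg.norm(z_lin - z_sc) < 1e-7
            assert abs(w_lin - w_sc) < 1e-7


def test_fixed_voronoi_adjacency_invariance():
    """The power-diagram region adjacency of B(t), labelled by (i, j)
    pairs, is the same at t = 0.25, 0.5, 0.75."""
    from skinmorph.regular_triangulation import build_regular_complex

    for seed in (1, 5, 9, 14, 23):
        src, tgt = random_morph_pair(seed, 2, 3)
        graphs = []
        for t in (0.25, 0.5, 0.75):
            bt = interpolate_ball_set(src, tgt, t, prune=True)
            rc = build_regular_complex(bt, seed=0)
            labels = [tuple(map(int, lab.split("x"))) for lab in bt.labels]
            edges = {
                frozenset(labels[i] for i in c.balls)
                for c in rc.cells
                if c.delaunay_dim == 1
            }
            graphs.append(edges)
        assert graphs[0] == graphs[1] == graphs[2], f"seed {seed}"


def test_single_ball_morph_closed_form():
    """Morphing one ball into another: every intermediate skin is the
    sphere of the interpolated ball, shrunk by sqrt(2)."""
    a = WeightedPoint(np.zeros(3), 4.0)
    b = WeightedPoint(np.array([1.5, 0.5, 0.0]), 9.0)
    src = BallSet([a.center], [a.weight])
    tgt = BallSet([b.center], [b.weight])
    states = generate_morph(src, tgt, MorphConfig(frame_count=6, mesh_resolution=0.2))
    for st in states[1:-1]:
        expect = wp_interpolate(a, b, st.t)
        r = np.linalg.norm(st.mesh.vertices - expect.center, axis=1)
        assert abs(r - np.sqrt(expect.weight / 2.0)).max() < 1e-6


def test_stationary_morph_vertices_do_not_drift():
    from skinmorph.io_pdb import random_ball_set

    src = random_ball_set(5, 42)
    tgt = BallSet(src.centers.copy(), src.weights.copy())
    states = generate_morph(src, tgt, MorphConfig(frame_count=5, mesh_resolution=0.3))
    m0 = states[0].mesh
    idx0 = {v: i for i, v in enumerate(m0.vertex_ids)}
    for st in states[1:-1]:
        idx1 = {v: i for i, v in enumerate(st.mesh.vertex_ids)}
        common = np.intersect1d(m0.vertex_ids, st.mesh.vertex_ids)
        assert len(common) > 0.9 * len(m0.vertices)
        drift = max(
            np.linalg.norm(m0.vertices[idx0[v]] - st.mesh.vertices[idx1[v]])
            for v in common
        )
        # a vertex reassigned across a mixed-cell facet moves by the square
        # of its distance to the facet, so the bound is 1e-5, not exact
        assert drift < 1e-5


def test_partial_movement_morph_runs_with_degenerate_cells():
    """Four atoms, one moves: coincident cells classify as degenerate and
    the morph completes without jittering the static atoms."""
    from skinmorph.regular_triangulation import build_regular_complex
    from skinmorph.superimposition import census

    c = np.array([[0, 0, 0], [2.2, 0, 0], [1.1, 1.9, 0], [1.1, 0.6, 1.8]], float)
    w = np.full(4, 2.9)
    src = BallSet(c, w)
    c2 = c.copy()
    c2[3] += np.array([0.8, -0.4, 0.5])
    tgt = BallSet(c2, w)
    inter = superimpose(build_regular_complex(src), build_regular_complex(tgt))
    cen = census(inter)
    degen = {k: v for k, v in cen.items() if k[2] > k[0] + k[1] - 3}
    assert degen, "partial movement must produce degenerate cells"
    states = generate_morph(src, tgt, MorphConfig(frame_count=5, mesh_resolution=0.3))
    assert len(states) == 5
    assert all(not st.mesh.is_empty for st in states)


def test_correspondence_integrity():
    """Every vertex id of frame k is present in frame k+1 or recorded as
    retired there; born ids are new."""
    src, tgt = random_morph_pair(3, 2, 3)
    states = generate_morph(src, tgt, MorphConfig(frame_count=6, mesh_resolution=0.3))
    seen: set[int] = set(states[0].mesh.vertex_ids.tolist())
    for prev, cur in zip(states, states[1:]):
        prev_ids = set(prev.mesh.vertex_ids.tolist())
        cur_ids = set(cur.mesh.vertex_ids.tolist())
        assert prev_ids <= cur_ids | set(cur.retired.tolist())
        assert not (set(cur.born.tolist()) & seen)
        seen |= cur_ids


def test_frame_to_frame_continuity_scales_with_step():
    """Max vertex displacement between consecutive frames roughly halves
    when the frame count doubles."""
    src, tgt = random_morph_pair(13, 2, 2)

    def max_step(frames):
        states = generate_morph(src, tgt, MorphConfig(frame_count=frames, mesh_resolution=0.3))
        steps = []
        for a, b in zip(states[1:-2], states[2:-1]):
            ia = {v: i for i, v in enumerate(a.mesh.vertex_ids)}
            ib = {v: i for i, v in enumerate(b.mesh.vertex_ids)}
            common = np.intersect1d(a.mesh.vertex_ids, b.mesh.vertex_ids)
            if len(common):
                steps.append(
                    max(
                        np.linalg.norm(a.mesh.vertices[ia[v]] - b.mesh.vertices[ib[v]])
                        for v in common
                    )
                )
        return max(steps)

    s100, s200 = max_step(12), max_step(23)
    assert s200 < s100
    assert s100 / s200 == pytest.approx(2.0, rel=0.35)


def test_empty_inputs_rejected():
    src = BallSet([[0, 0, 0]], [1.0])
    with pytest.raises(Exception):
        interpolate_ball_set(src, src, 2.0)
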