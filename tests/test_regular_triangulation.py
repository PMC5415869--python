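"""Weighted Delaunay / power diagram construction and predicates."""

import itertools

import numpy as np
import pytest

from skinmorph.io_pdb import random_ball_set
from skinmorph.regular_triangulation import (
    DegeneracyError,
    build_regular_complex,
    classify_point,
    classify_points,
    orthogonal_ball,
    orthosphere_check,
)
from skinmorph.wp_algebra import BallSet


def test_two_ball_complex(symmetric_pair):
    rc = build_regular_complex(symmetric_pair)
    assert rc.census() == {0: 2, 1: 1}
    edge = rc.cell((0, 1))
    assert edge.voronoi_dim == 2          # the bisector plane x = 0
    assert np.allclose(edge.vertices[:, 0], 0.0, atol=1e-7)
    assert all(rc.cell((i,)).unbounded for i in range(2))
    assert rc.redundant_balls == []


def test_regular_tetrahedron_complex(unit_tetrahedron):
    rc = build_regular_complex(unit_tetrahedron)
    assert rc.census() == {0: 4, 1: 6, 2: 4, 3: 1}
    v = rc.cell((0, 1, 2, 3))
    assert v.voronoi_dim == 0
    assert np.allclose(v.vertices[0], 0.0, atol=1e-7)  # power centre = centroid


def test_coincident_centres_rejected():
    with pytest.raises(DegeneracyError):
        build_regular_complex(BallSet([[0, 0, 0], [0, 0, 0]], [1.0, 2.0]))


def test_voronoi_vertex_is_power_centre():
    """Each bounded Voronoi vertex has equal power distance to its 4 balls,
    strictly smaller than to every other ball."""
    balls = random_ball_set(12, seed=5, spread=1.6)
    rc = build_regular_complex(balls)
    tets = [c for c in rc.cells if c.delaunay_dim == 3]
    assert tets
    for c in tets:
        z = c.vertices[0]
        pd = balls.power_distances(z)
        inside = pd[list(c.balls)]
        outside = np.delete(pd, list(c.balls))
        assert np.ptp(inside) < 1e-6
        if len(outside):
            assert outside.min() > inside.max() - 1e-6


def test_orthosphere_emptiness_oracle():
    """Every tetrahedron reported by the builder passes the brute-force
    empty-orthosphere check, and no rejected 4-subset whose power vertex
    falls inside the clipping box is missed (exhaustive enumeration on
    small sets; sliver tetrahedra with power vertices beyond the box are
    legitimately absent from the clipped realisation)."""
    for seed in (0, 1):
        balls = random_ball_set(8, seed=seed, spread=1.5)
        rc = build_regular_complex(balls)
        lo, hi = rc.bbox
        reported = {c.balls for c in rc.cells if c.delaunay_dim == 3}
        assert all(orthosphere_check(t, balls) for t in reported)
        for tet in itertools.combinations(range(8), 4):
            try:
                z, _ = orthogonal_ball(tet, balls)
                ok = orthosphere_check(tet, balls)
            except DegeneracyError:
                continue
            if np.any(z < lo) or np.any(z > hi):
                continue
            assert (tet in reported) == ok, tet


def test_orthosphere_dominating_ball(unit_tetrahedron):
    assert orthosphere_check((0, 1, 2, 3), unit_tetrahedron)
    centers = np.vstack([unit_tetrahedron.centers, [[0, 0, 0]]])
    weights = np.append(unit_tetrahedron.weights, 50.0)
    crowded = BallSet(centers, weights)
    assert not orthosphere_check((0, 1, 2, 3), crowded)


def test_orthogonal_ball_requires_independent_centres():
    flat = BallSet([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], np.ones(4))
    with pytest.raises(DegeneracyError):
        orthogonal_ball((0, 1, 2, 3), flat)


def test_classify_point_basics(symmetric_pair):
    assert classify_point(np.array([-5.0, 0, 0]), symmetric_pair).index == 0
    loc = classify_point(np.array([0.0, 3.0, -1.0]), symmetric_pair)
    assert loc.tie and loc.index == 0


def test_classify_point_matches_cell_membership():
    """argmin-power labels agree with geometric membership in the realised
    power cells for thousands of random points."""
    balls = random_ball_set(10, seed=3, spread=1.8)
    rc = build_regular_complex(balls)
    rng = np.random.default_rng(0)
    lo, hi = balls.bounding_box(2.0)
    pts = rng.uniform(lo, hi, size=(10000, 3))
    labels = classify_points(pts, balls)
    for i in range(len(balls)):
        cell = rc.cell((i,))
        mine = pts[labels == i]
        if cell is None:
            assert len(mine) == 0
            continue
        slack = cell.poly.b_ub[None, :] - mine @ cell.poly.A_ub.T
        assert slack.min() > -1e-7


def test_complex_invariant_under_rigid_motion():
    balls = random_ball_set(9, seed=11, spread=1.6)
    rc = build_regular_complex(balls)
    th = 0.61
    R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    moved = BallSet(balls.centers @ R.T + np.array([3.0, -1.0, 2.0]), balls.weights)
    rc2 = build_regular_complex(moved)
    assert {c.balls for c in rc.cells} == {c.balls for c in rc2.cells}


def test_redundant_ball_detection():
    """A small ball buried inside a big one has an empty power cell."""
    balls = BallSet([[0, 0, 0], [0.1, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]],
                    [9.0, 0.01, 1.0, 1.0, 1.0])
    rc = build_regular_complex(balls)
    assert 1 in rc.redundant_balls
    assert all(1 not in c.balls for c in rc.cells)
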