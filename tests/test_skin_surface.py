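"""Quadric patches, global field continuity, and mesh extraction."""

import numpy as np
import pytest

from skinmorph.io_pdb import random_ball_set
from skinmorph.mixed_complex import build_mixed_cells
from skinmorph.regular_triangulation import build_regular_complex
from skinmorph.skin_surface import (
    QuadricPatch,
    implicit_value,
    locate_mixed_cell,
    mesh_hausdorff,
    mesh_skin,
    skin_field,
)
from skinmorph.wp_algebra import BallSet


def _cells(balls):
    return build_mixed_cells(build_regular_complex(balls))


def test_single_ball_sphere_patch():
    """The skin of one ball of weight 8 is the sphere of radius 2."""
    cells = _cells(BallSet([[0, 0, 0]], [8.0]))
    (cell,) = cells
    assert implicit_value(np.array([2.0, 0, 0]), cell) == pytest.approx(0.0)
    assert implicit_value(cell.center, cell) == pytest.approx(-4.0)  # -R^2 at centre
    patch = QuadricPatch.from_cell(cell)
    assert patch.kind == "sphere" and patch.R2 == pytest.approx(4.0)


def test_hyperboloid_patch_on_axis(symmetric_pair):
    cells = {c.balls: c for c in _cells(symmetric_pair)}
    edge = cells[(0, 1)]
    # on the symmetry axis at distance d from the centre: value -d^2 - R^2
    d = 0.7
    x = edge.center + d * np.array([1.0, 0, 0])
    assert implicit_value(x, edge) == pytest.approx(-d * d - edge.weight / 2.0)
    patch = QuadricPatch.from_cell(edge)
    assert patch.kind == "hyperboloid" and patch.sheet_sign == 1


def test_locate_mixed_cell(symmetric_pair):
    cells = _cells(symmetric_pair)
    by_balls = {c.balls: c.cell_id for c in cells}
    assert locate_mixed_cell(np.array([-1.0, 0, 0]), cells) == by_balls[(0,)]
    assert locate_mixed_cell(np.array([0.0, 0, 0]), cells) == by_balls[(0, 1)]
    with pytest.raises(ValueError):
        locate_mixed_cell(np.array([500.0, 0, 0]), cells)


def test_field_continuity_across_facets():
    """The per-cell quadric values agree at points on shared mixed-cell
    facets (the skin's global field is continuous)."""
    balls = random_ball_set(6, seed=4, spread=1.4)
    cells = _cells(balls)
    rng = np.random.default_rng(2)
    checked = 0
    for c in cells:
        for _ in range(40):
            lam = rng.dirichlet(np.ones(len(c.vertices)))
            p = lam @ c.vertices
            slacks = c.b - c.A @ p
            k = int(np.argmin(slacks))
            p_facet = p + slacks[k] * c.A[k]      # push onto the nearest facet
            vals = [
                implicit_value(p_facet, other)
                for other in cells
                if (other.b - other.A @ p_facet).min() > -1e-7
            ]
            if len(vals) >= 2:
                checked += 1
                assert max(vals) - min(vals) < 1e-6
    assert checked >= 200


def test_single_ball_mesh_radius_and_genus():
    balls = BallSet([[0, 0, 0]], [8.0])
    cells = _cells(balls)
    mesh = mesh_skin(cells, 0.2, balls.bounding_box(3.2))
    r = np.linalg.norm(mesh.vertices, axis=1)
    assert abs(r - 2.0).max() < 0.01
    assert mesh.component_count() == 1
    assert mesh.euler_characteristic() == 2       # genus 0
    assert mesh.max_edge_triangle_count() <= 2    # edge-manifold


def test_component_split_far_vs_near():
    far = BallSet([[-4, 0, 0], [4, 0, 0]], [2.0, 2.0])
    near = BallSet([[-1, 0, 0], [1, 0, 0]], [2.0, 2.0])
    for balls, expected in ((far, 2), (near, 1)):
        cells = _cells(balls)
        mesh = mesh_skin(cells, 0.15, balls.bounding_box(2.5))
        assert mesh.component_count() == expected


def test_mesh_error_decreases_with_resolution():
    balls = BallSet([[0, 0, 0]], [8.0])
    cells = _cells(balls)
    errs = []
    for res in (0.4, 0.2):
        mesh = mesh_skin(cells, res, balls.bounding_box(3.2))
        r = np.linalg.norm(mesh.vertices, axis=1)
        # Hausdorff to the analytic sphere: vertex radial error (projection
        # puts vertices on the sphere) plus the mesh chord sag
        errs.append(abs(r - 2.0).max() + res**2 / 4.0)
    assert errs[1] < errs[0]


def test_empty_surface_is_not_an_error():
    cells = _cells(BallSet([[0, 0, 0]], [-4.0]))
    mesh = mesh_skin(cells, 0.3, (np.full(3, -2.0), np.full(3, 2.0)))
    assert mesh.is_empty


def test_skin_inside_inflated_hull():
    balls = random_ball_set(7, seed=9, spread=1.5)
    cells = _cells(balls)
    mesh = mesh_skin(cells, 0.25, balls.bounding_box(balls.max_radius + 1.0))
    lo, hi = balls.bounding_box(balls.max_radius)
    assert np.all(mesh.vertices >= lo - 1e-6) and np.all(mesh.vertices <= hi + 1e-6)


def test_mesh_hausdorff_identity_and_offset():
    balls = BallSet([[0, 0, 0]], [8.0])
    cells = _cells(balls)
    mesh = mesh_skin(cells, 0.25, balls.bounding_box(3.2))
    assert mesh_hausdorff(mesh, mesh) == pytest.approx(0.0, abs=1e-12)
    import dataclasses

    shifted = dataclasses.replace(
        mesh, vertices=mesh.vertices + np.array([0.1, 0, 0]),
        triangles=mesh.triangles.copy(), vertex_cell=mesh.vertex_cell.copy(),
    )
    d = mesh_hausdorff(mesh, shifted)
    assert 0.0 < d <= 0.1 + 1e-9
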