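"""Mixed cells: half-scaled Minkowski sums of dual Delaunay/Voronoi pairs.

For a dual pair (delta_X, v_X) the mixed cell is
``mu_X = (delta_X + v_X) / 2``.  The mixed cells of a complex tile space,
and inside each one the skin surface is a single quadric patch whose
centre is ``z_X = aff(delta_X) ∩ aff(v_X)`` and whose size parameter is
the mixed-cell weight ``w_X = w_i - ||z_X - z_i||^2`` for any ball i of X
(the two affine hulls are orthogonal complements through z_X, so w_X does
not depend on the representative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._polyhedra import hull_halfspaces, min_margin
from .constants import RANK_TOL
from .regular_triangulation import DegeneracyError, RegularComplex, VoronoiCell
from .wp_algebra import BallSet, WeightedPoint

__all__ = ["MixedCell", "build_mixed_cells", "mixed_cell_center", "mixed_cell_weight"]


@dataclass
class MixedCell:
    """A mixed cell with its quadric-patch data.

    ``mtype`` is the Voronoi-cell dimension (3: ball region / sphere,
    2: face / hyperboloid, 1: edge / hyperboloid, 0: vertex / sphere).
    ``axes_delaunay`` spans the Delaunay affine hull direction (the
    symmetry subspace of the patch); its orthogonal complement spans the
    Voronoi direction.
    """

    cell_id: int
    balls: tuple[int, ...]            # defining ball indices (source cells)
    mtype: int
    center: np.ndarray                # z_X
    weight: float                     # w_X
    axes_delaunay: np.ndarray         # (k, 3) orthonormal rows, k = dim delta_X
    A: np.ndarray                     # polytope half-spaces A x <= b
    b: np.ndarray
    vertices: np.ndarray              # polytope vertices

    @property
    def patch_kind(self) -> str:
        return "sphere" if self.mtype in (3, 0) else "hyperboloid"

    def contains(self, x: np.ndarray, tol: float = 1e-9) -> bool:
        return bool(min_margin(np.asarray(x, float)[None, :], self.A, self.b)[0] >= -tol)


def delaunay_subspace(centers: np.ndarray, tol: float = RANK_TOL) -> np.ndarray:
    """Orthonormal basis (k, 3) of the direction space of aff(centers)."""
    if len(centers) == 1:
        return np.zeros((0, 3))
    d = centers - centers.mean(axis=0)
    _, s, vt = np.linalg.svd(d, full_matrices=False)
    rank = int(np.sum(s > tol * max(1.0, s[0])))
    return vt[:rank]


def mixed_cell_center(X, balls: BallSet, tol: float = 1e-6) -> np.ndarray:
    """Intersection of aff(delta_X) with aff(v_X).

    aff(v_X) is the equal-power locus of the balls of X, so z_X is the
    unique point of the centres' affine hull with equal power distance to
    every ball of X.
    """
    X = tuple(X)
    centers = balls.centers[list(X)]
    if len(X) == 1:
        return centers[0].copy()
    z0 = centers.mean(axis=0)
    M = delaunay_subspace(centers).T          # (3, k)
    i0 = X[0]
    zi0, hi0 = balls.centers[i0], float(balls.centers[i0] @ balls.centers[i0]) - balls.weights[i0]
    rows, rhs = [], []
    for j in X[1:]:
        zj = balls.centers[j]
        hj = float(zj @ zj) - balls.weights[j]
        rows.append(2.0 * (zj - zi0))
        rhs.append(hj - hi0)
    A = np.array(rows)
    b = np.array(rhs) - A @ z0
    AM = A @ M
    u, res, rank, _ = np.linalg.lstsq(AM, b, rcond=None)
    z = z0 + M @ u
    if np.max(np.abs(A @ z - (np.array(rhs)))) > tol * max(1.0, np.abs(rhs).max() if len(rhs) else 1.0):
        raise DegeneracyError("affine hulls of the dual pair do not meet at a point")
    return z


def mixed_cell_weight(z_X: np.ndarray, ball: WeightedPoint) -> float:
    """w_X = w_i - ||z_X - z_i||^2 for a representative ball of X."""
    d = np.asarray(z_X, float) - ball.center
    return float(ball.weight - d @ d)


def _checked_weight(z_X: np.ndarray, X, balls: BallSet, tol: float = 1e-6) -> float:
    ws = [mixed_cell_weight(z_X, balls[i]) for i in X]
    if max(ws) - min(ws) > tol * max(1.0, abs(ws[0])):
        raise DegeneracyError(
            f"mixed-cell weight inconsistent across representative balls of {tuple(X)}"
        )
    return float(np.mean(ws))


def _minkowski_halved(delta_verts: np.ndarray, voronoi_verts: np.ndarray):
    pts = 0.5 * (delta_verts[:, None, :] + voronoi_verts[None, :, :]).reshape(-1, 3)
    return hull_halfspaces(pts)


def build_mixed_cells(rc: RegularComplex, balls: BallSet | None = None) -> list[MixedCell]:
    """One mixed cell per dual Delaunay/Voronoi pair of the complex.

    Unbounded Voronoi cells enter through their clipped realisation; the
    clipping box is generous enough that the skin never reaches the cut.
    """
    balls = balls if balls is not None else rc.balls
    cells: list[MixedCell] = []
    for cid, vc in enumerate(rc.cells):
        cells.append(make_mixed_cell(cid, vc, balls))
    return cells


def make_mixed_cell(cid: int, vc: VoronoiCell, balls: BallSet) -> MixedCell:
    X = vc.balls
    centers = balls.centers[list(X)]
    z = mixed_cell_center(X, balls)
    w = _checked_weight(z, X, balls)
    E = delaunay_subspace(centers)
    A, b, verts = _minkowski_halved(centers, vc.vertices)
    return MixedCell(cid, X, vc.voronoi_dim, z, w, E, A, b, verts)
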