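"""Weighted Delaunay complex and its dual power (Voronoi) diagram.

The power cell of ball ``b_i`` is ``v_i = {x : pi_i(x) <= pi_j(x) for all j}``
and the cell of a subset ``X`` is the intersection of its members' cells.
The dual Delaunay cell of ``v_X`` is the convex hull of the centres of
``X``; under the traditional general-position (TGP) assumption every
Delaunay cell is a simplex with ``card(X) = dim + 1`` and the cells come
in exactly four types: vertex, edge, triangle, tetrahedron.

Construction uses the classical lifting map: ball ``(z, w)`` lifts to the
4-space point ``(z, ||z||^2 - w)``; the lower convex-hull facets are the
regular-triangulation tetrahedra.  Small or degenerate inputs fall back
to direct subset enumeration with linear-programming emptiness tests,
which doubles as an independent construction for low ball counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from ._polyhedra import Polyhedron, box_halfspaces, classify_polyhedron, realize_vertices
from .constants import JITTER_SCALE, RANK_TOL, TOL_ABS
from .wp_algebra import BallSet

__all__ = [
    "VoronoiCell",
    "RegularComplex",
    "build_regular_complex",
    "orthosphere_check",
    "orthogonal_ball",
    "classify_point",
    "PointLocation",
]


class DegeneracyError(ValueError):
    """Raised when an input configuration defeats the geometric construction."""


@dataclass
class VoronoiCell:
    """One dual pair: Delaunay cell over ``balls`` and its power cell."""

    balls: tuple[int, ...]           # defining ball indices X, sorted
    voronoi_dim: int                 # realised dimension of v_X
    poly: Polyhedron                 # classified constraint form (incl. clip box)
    vertices: np.ndarray             # realised vertices, clipped to the box
    unbounded: bool                  # touches the clipping box
    delaunay_dim: int = -1           # affine rank of the centres of X

    def __post_init__(self) -> None:
        if self.delaunay_dim < 0:
            self.delaunay_dim = len(self.balls) - 1

    @property
    def witness(self) -> np.ndarray:
        return self.poly.witness


@dataclass
class RegularComplex:
    """Paired weighted Delaunay complex and power diagram of a ball set."""

    balls: BallSet
    cells: list[VoronoiCell]
    redundant_balls: list[int]
    bbox: tuple[np.ndarray, np.ndarray]
    jitter_applied: bool = False
    _by_X: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_X = {c.balls: c for c in self.cells}

    def cell(self, X) -> VoronoiCell | None:
        return self._by_X.get(tuple(sorted(X)))

    def cells_of_delaunay_dim(self, k: int) -> list[VoronoiCell]:
        return [c for c in self.cells if c.delaunay_dim == k]

    def census(self) -> dict[int, int]:
        """Delaunay cell-type census: dimension -> count."""
        out: dict[int, int] = {}
        for c in self.cells:
            out[c.delaunay_dim] = out.get(c.delaunay_dim, 0) + 1
        return out

    def to_json_dict(self) -> dict:
        return {
            "n_balls": len(self.balls),
            "redundant": list(self.redundant_balls),
            "cells": [
                {"balls": list(c.balls), "voronoi_dim": c.voronoi_dim, "unbounded": c.unbounded}
                for c in self.cells
            ],
        }


def _lifted(balls: BallSet) -> np.ndarray:
    h = np.einsum("ij,ij->i", balls.centers, balls.centers) - balls.weights
    return np.hstack([balls.centers, h[:, None]])


def bisector(balls: BallSet, i: int, j: int) -> tuple[np.ndarray, float]:
    """Radical plane pi_i(x) = pi_j(x) as (a, b) with a.x = b."""
    zi, zj = balls.centers[i], balls.centers[j]
    hi = float(zi @ zi) - balls.weights[i]
    hj = float(zj @ zj) - balls.weights[j]
    return 2.0 * (zj - zi), hj - hi


def cell_constraints(
    balls: BallSet, X: tuple[int, ...], others: np.ndarray, bbox
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Constraint form of v_X: equal power inside X, dominated outside."""
    i0 = X[0]
    eq_rows, eq_rhs = [], []
    for j in X[1:]:
        a, b = bisector(balls, i0, j)
        eq_rows.append(a)
        eq_rhs.append(b)
    ub_rows, ub_rhs = [], []
    for k in others:
        if k in X:
            continue
        a, b = bisector(balls, i0, int(k))
        ub_rows.append(a)
        ub_rhs.append(b)
    A_box, b_box = box_halfspaces(*bbox)
    A_ub = np.vstack([ub_rows, A_box]) if ub_rows else A_box
    b_ub = np.concatenate([ub_rhs, b_box]) if ub_rows else b_box
    A_eq = np.array(eq_rows) if eq_rows else np.zeros((0, 3))
    b_eq = np.array(eq_rhs) if eq_rows else np.zeros(0)
    return A_ub, b_ub, A_eq, b_eq


def default_bbox(balls: BallSet, extra: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Clipping box: centre extent inflated by the diameter plus 3 max radii.

    The inflation keeps every point of interest for skin evaluation (the
    skin lies inside conv(centres) dilated by the largest radius) strictly
    representable by half-scaled Minkowski sums of clipped cells.
    """
    lo, hi = balls.bounding_box()
    diam = float(np.linalg.norm(hi - lo))
    # the half-scaled Minkowski sums of clipped cells must still cover the
    # skin neighbourhood (extent + max radius + mesh margin); a clip pad of
    # diameter + 3 r_max + 4 guarantees that with room to spare
    pad = diam + 3.0 * balls.max_radius + 4.0 + extra
    return lo - pad, hi + pad


def _tie_set(balls: BallSet, x: np.ndarray, tol: float = 1e-6) -> tuple[int, ...]:
    pd = balls.power_distances(x)
    return tuple(np.flatnonzero(pd <= pd.min() + tol))


def _tets_by_lifting(balls: BallSet) -> list[tuple[int, ...]]:
    pts = _lifted(balls)
    hull = ConvexHull(pts, qhull_options="Qt")
    lower = hull.equations[:, 3] < -1e-12  # 4th normal component: lower hull
    tets = [tuple(sorted(map(int, s))) for s, low in zip(hull.simplices, lower) if low]
    return tets


def build_regular_complex(
    balls: BallSet, seed: int = 0, jitter: bool = True
) -> RegularComplex:
    """Build the weighted Delaunay complex and dual power diagram.

    Generic inputs of five or more balls go through the lifting map;
    smaller inputs (whose complex is legitimately lower-dimensional) are
    enumerated subset by subset with LP emptiness tests.  Cospherical or
    otherwise degenerate inputs that defeat the convex hull are retried
    once with a deterministic jitter of magnitude ``1e-8`` Angstrom drawn
    from ``seed``; the jitter is recorded on the returned complex.
    """
    n = len(balls)
    spread = np.ptp(balls.centers, axis=0).max() if n > 1 else 0.0
    if n > 1 and spread < 1e-12:
        raise DegeneracyError("all ball centres coincide")
    jitter_applied = False

    if n >= 5:
        try:
            tets = _tets_by_lifting(balls)
        except QhullError:
            if not jitter:
                raise DegeneracyError("degenerate input and jitter disabled")
            # the jitter is used only to discover candidate subsets via the
            # convex hull; all cells are classified against the exact input,
            # so coincident features stay coincident (and get merged into
            # canonical non-simplicial cells) instead of becoming slivers
            rng = np.random.default_rng(seed)
            hull_balls = BallSet(
                balls.centers + JITTER_SCALE * rng.standard_normal(balls.centers.shape),
                balls.weights,
                list(balls.labels),
            )
            jitter_applied = True
            try:
                tets = _tets_by_lifting(hull_balls)
            except QhullError as exc:  # pragma: no cover
                raise DegeneracyError(f"degenerate input: {exc}") from exc
        subsets: set[tuple[int, ...]] = set()
        for tet in tets:
            for r in (1, 2, 3, 4):
                subsets.update(itertools.combinations(tet, r))
        candidates = sorted(subsets, key=lambda X: (len(X), X))
    else:
        tets = (
            [tuple(range(4))] if n == 4 else []
        )
        candidates = [
            X
            for r in range(1, min(n, 4) + 1)
            for X in itertools.combinations(range(n), r)
        ]

    # the clip box must contain every bounded power vertex, else the dual
    # tetrahedron cell is lost and the mixed tiling acquires a (distant)
    # hole; expand to cover all finite orthocentres, with a sanity cap
    bbox = default_bbox(balls)
    lo, hi = bbox
    cap = 100.0 * (float(np.linalg.norm(hi - lo)) + 1.0)
    for tet in tets:
        try:
            z, _ = orthogonal_ball(tet, balls)
        except DegeneracyError:
            continue
        if np.all(np.abs(z) < cap):
            lo = np.minimum(lo, z - 1.0)
            hi = np.maximum(hi, z + 1.0)
    bbox = (lo, hi)

    all_idx = np.arange(n)
    cells: list[VoronoiCell] = []
    registered: set[tuple[int, ...]] = set()
    seen_balls: set[int] = set()
    for X in candidates:
        A_ub, b_ub, A_eq, b_eq = cell_constraints(balls, X, all_idx, bbox)
        poly = classify_polyhedron(A_ub, b_ub, A_eq, b_eq)
        if poly is None:
            continue
        # canonical labelling: a relative-interior point of v_X ties on the
        # maximal equal-power set X*.  Generically X* == X; for degenerate
        # (cospherical) inputs the split simplices sharing one power-diagram
        # feature are merged into a single non-simplicial cell under X*.
        X_star = _tie_set(balls, poly.witness)
        if not set(X) <= set(X_star):
            continue
        if X_star in registered:
            continue
        registered.add(X_star)
        verts = realize_vertices(poly)
        lo, hi = bbox
        on_box = bool(
            np.any(verts <= lo + 1e-6) or np.any(verts >= hi - 1e-6)
        )
        d = balls.centers[list(X_star)]
        ddim = 0
        if len(X_star) > 1:
            _, s, _ = np.linalg.svd(d - d.mean(axis=0))
            ddim = int(np.sum(s > RANK_TOL * max(1.0, s[0])))
        cells.append(VoronoiCell(X_star, poly.dim, poly, verts, on_box, ddim))
        seen_balls.update(X_star)
    redundant = sorted(set(range(n)) - seen_balls)
    return RegularComplex(balls, cells, redundant, bbox, jitter_applied)


def orthogonal_ball(cell: tuple[int, ...], balls: BallSet) -> tuple[np.ndarray, float]:
    """Centre and weight of the ball orthogonal to four balls.

    The orthogonal ball has equal power distance from its centre to each
    of the four, that common distance being its own weight.
    """
    X = tuple(cell)
    if len(X) != 4:
        raise ValueError("orthogonal ball requires exactly 4 ball indices")
    i0 = X[0]
    A = np.array([bisector(balls, i0, j)[0] for j in X[1:]])
    b = np.array([bisector(balls, i0, j)[1] for j in X[1:]])
    if abs(np.linalg.det(A)) < 1e-10 * max(1.0, np.abs(A).max()) ** 3:
        raise DegeneracyError("affinely dependent centres: no unique orthocentre")
    z = np.linalg.solve(A, b)
    d = z - balls.centers[i0]
    w = float(d @ d) - balls.weights[i0]
    return z, w


def orthosphere_check(cell: tuple[int, ...], balls: BallSet, tol: float = TOL_ABS) -> bool:
    """Empty-orthosphere predicate for a candidate tetrahedron.

    True iff no fifth ball has smaller power distance to the orthocentre
    than the orthogonal ball's weight.
    """
    z, w = orthogonal_ball(cell, balls)
    others = [i for i in range(len(balls)) if i not in cell]
    if not others:
        return True
    pd = balls.power_distances(z)[others]
    return bool(np.all(pd >= w - tol))


class PointLocation(NamedTuple):
    index: int
    tie: bool


def classify_point(x: np.ndarray, balls: BallSet, tol: float = TOL_ABS) -> PointLocation:
    """Index of the ball whose power cell contains x (lowest index on ties)."""
    pd = balls.power_distances(np.asarray(x, dtype=float))
    i = int(np.argmin(pd))
    tie = bool(np.sum(pd <= pd[i] + tol) > 1)
    return PointLocation(i, tie)


def classify_points(xs: np.ndarray, balls: BallSet) -> np.ndarray:
    """Vectorised region labels (argmin power, lowest index on ties)."""
    return np.argmin(balls.power_distances(np.atleast_2d(xs)), axis=1)
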