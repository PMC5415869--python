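"""Internal polyhedral kernel.

Closed convex polyhedra are handled in constraint form ``A_ub x <= b_ub``,
``A_eq x = b_eq`` inside a clipping box.  The routines here answer the
questions the geometric modules need:

* is the polyhedron empty?
* what is its affine dimension (implicit equalities included)?
* a relative-interior witness point,
* its vertices, realised inside the clipping box.

Everything is numerical: linear programs (HiGHS via scipy) decide
feasibility and implicit equalities, and an SVD decides affine rank.
Inequality rows are normalised to unit normals so that slacks are
Euclidean distances and one tolerance applies throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .constants import RANK_TOL

__all__ = [
    "Polyhedron",
    "box_halfspaces",
    "normalize_rows",
    "classify_polyhedron",
    "realize_vertices",
    "hull_halfspaces",
    "min_margin",
]

_LP_OPTS = {"presolve": True}


def normalize_rows(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each constraint row to a unit normal; drop zero rows."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.asarray(b, dtype=float).ravel()
    if A.size == 0:
        return A.reshape(0, 3), b
    norms = np.linalg.norm(A, axis=1)
    keep = norms > 1e-14
    return A[keep] / norms[keep, None], b[keep] / norms[keep]


def box_halfspaces(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned box as 6 half-spaces A x <= b."""
    eye = np.eye(3)
    A = np.vstack([eye, -eye])
    b = np.concatenate([np.asarray(hi, float), -np.asarray(lo, float)])
    return A, b


@dataclass
class Polyhedron:
    """A classified polyhedron: dimension, witness, and constraint split."""

    dim: int
    witness: np.ndarray          # relative-interior point
    A_eq: np.ndarray             # explicit + implicit equalities (unit rows)
    b_eq: np.ndarray
    A_ub: np.ndarray             # non-implicit inequalities (unit rows)
    b_ub: np.ndarray
    radius: float                # Chebyshev radius within the affine hull


def _nullspace(A: np.ndarray, tol: float = RANK_TOL) -> np.ndarray:
    """Orthonormal basis (3, k) of the null space of A (or identity if empty)."""
    if A.size == 0:
        return np.eye(3)
    _, s, vt = np.linalg.svd(A)
    rank = int(np.sum(s > tol * max(1.0, s[0] if len(s) else 1.0)))
    return vt[rank:].T


def _affine_point(A_eq: np.ndarray, b_eq: np.ndarray) -> np.ndarray | None:
    """Least-squares point on the affine subspace; None if inconsistent."""
    if A_eq.size == 0:
        return np.zeros(3)
    x, *_ = np.linalg.lstsq(A_eq, b_eq, rcond=None)
    if np.max(np.abs(A_eq @ x - b_eq)) > 1e-6:
        return None
    return x


def _chebyshev(
    A_ub: np.ndarray,
    b_ub: np.ndarray,
    x0: np.ndarray,
    Q: np.ndarray,
    r_cap: float = 1.0,
) -> tuple[np.ndarray, float] | None:
    """Largest inscribed ball within the affine subspace x = x0 + Q u.

    Returns (centre point in R^3, radius); None if infeasible.
    Constraints parallel to the subspace are checked at x0 and dropped.
    """
    k = Q.shape[1]
    if k == 0:
        if A_ub.size and np.any(A_ub @ x0 - b_ub > 1e-7):
            return None
        return x0, 0.0
    if A_ub.size == 0:
        return x0, r_cap
    Au = A_ub @ Q                       # (m, k)
    bu = b_ub - A_ub @ x0
    proj = np.linalg.norm(Au, axis=1)
    parallel = proj <= 1e-10
    if np.any(bu[parallel] < -1e-7):
        return None
    Au, bu, proj = Au[~parallel], bu[~parallel], proj[~parallel]
    if len(bu) == 0:
        return x0, r_cap
    # vars (u, r): maximise r  s.t.  Au u + r*proj <= bu, 0 <= r <= r_cap
    c = np.zeros(k + 1)
    c[-1] = -1.0
    A_lp = np.hstack([Au, proj[:, None]])
    bounds = [(None, None)] * k + [(0.0, r_cap)]
    res = linprog(c, A_ub=A_lp, b_ub=bu, bounds=bounds, method="highs", options=_LP_OPTS)
    if not res.success:
        return None
    u, r = res.x[:k], res.x[-1]
    return x0 + Q @ u, float(r)


def _max_slack(
    row: int, A_ub: np.ndarray, b_ub: np.ndarray, x0: np.ndarray, Q: np.ndarray
) -> float:
    """max over the polyhedron of b_i - a_i.x (slack of one inequality)."""
    k = Q.shape[1]
    if k == 0:
        return float(b_ub[row] - A_ub[row] @ x0)
    c = A_ub[row] @ Q  # minimise a.x  <=> minimise c.u
    bu = b_ub - A_ub @ x0
    res = linprog(
        c,
        A_ub=A_ub @ Q,
        b_ub=bu,
        bounds=[(None, None)] * k,
        method="highs",
        options=_LP_OPTS,
    )
    if not res.success:  # unbounded below => unlimited slack
        return np.inf
    return float(bu[row] - res.fun)


def classify_polyhedron(
    A_ub: np.ndarray,
    b_ub: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    tol: float = RANK_TOL,
) -> Polyhedron | None:
    """Dimension + relative-interior witness of {A_ub x <= b_ub, A_eq x = b_eq}.

    Returns None when empty.  The clipping box must already be part of
    ``A_ub`` so the polyhedron is bounded.
    """
    A_ub, b_ub = normalize_rows(A_ub, b_ub)
    A_eq, b_eq = normalize_rows(A_eq, b_eq)
    x0 = _affine_point(A_eq, b_eq)
    if x0 is None:
        return None
    Q = _nullspace(A_eq)
    got = _chebyshev(A_ub, b_ub, x0, Q)
    if got is None:
        return None
    witness, r = got
    if r > tol:
        return Polyhedron(Q.shape[1], witness, A_eq, b_eq, A_ub, b_ub, r)
    # flat within the subspace: hunt for implicit equalities row by row
    implicit = np.zeros(len(b_ub), dtype=bool)
    for i in range(len(b_ub)):
        if _max_slack(i, A_ub, b_ub, x0, Q) <= tol:
            implicit[i] = True
    if not implicit.any():
        # numerically flat but no single implicit row; treat as degenerate point
        return Polyhedron(0, witness, A_eq, b_eq, A_ub, b_ub, 0.0)
    A_eq2 = np.vstack([A_eq, A_ub[implicit]]) if A_eq.size else A_ub[implicit]
    b_eq2 = np.concatenate([b_eq, b_ub[implicit]]) if A_eq.size else b_ub[implicit]
    x1 = _affine_point(A_eq2, b_eq2)
    if x1 is None:
        return None
    Q2 = _nullspace(A_eq2)
    got2 = _chebyshev(A_ub[~implicit], b_ub[~implicit], x1, Q2)
    if got2 is None:
        return None
    witness2, r2 = got2
    dim = Q2.shape[1] if r2 > tol else 0
    return Polyhedron(dim, witness2, A_eq2, b_eq2, A_ub[~implicit], b_ub[~implicit], r2)


def realize_vertices(poly: Polyhedron) -> np.ndarray:
    """Vertices (m, 3) of a classified bounded polyhedron.

    The polyhedron is parameterised over its affine hull and the vertex
    enumeration runs in that k-dimensional chart.
    """
    x0 = _affine_point(poly.A_eq, poly.b_eq)
    Q = _nullspace(poly.A_eq)
    k = Q.shape[1]
    if k == 0 or poly.dim == 0:
        return poly.witness[None, :]
    Au = poly.A_ub @ Q
    bu = poly.b_ub - poly.A_ub @ x0
    keep = np.linalg.norm(Au, axis=1) > 1e-10
    Au, bu = Au[keep], bu[keep]
    if k == 1:
        lo, hi = -np.inf, np.inf
        for a, b in zip(Au[:, 0], bu):
            if a > 0:
                hi = min(hi, b / a)
            else:
                lo = max(lo, b / a)
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("unbounded 1-d cell; clipping box missing")
        us = np.array([[lo], [hi]])
    else:
        interior_u = Q.T @ (poly.witness - x0)
        hs = np.hstack([Au, -bu[:, None]])
        try:
            hi_obj = HalfspaceIntersection(hs, interior_u)
            pts = hi_obj.intersections
            hull = ConvexHull(pts, qhull_options="QJ" if k == 2 else None)
            us = pts[hull.vertices]
        except QhullError:
            # fall back: degenerate chart, return witness only
            return poly.witness[None, :]
    return x0 + us @ Q.T


def hull_halfspaces(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Half-space form (A x <= b) of the convex hull of full-dim points.

    Returns (A, b, hull_vertices).  Falls back to joggled input when the
    point set is degenerate for qhull.
    """
    vertices = np.asarray(vertices, dtype=float)
    try:
        hull = ConvexHull(vertices)
    except QhullError:
        hull = ConvexHull(vertices, qhull_options="QJ")
    A = hull.equations[:, :3]
    b = -hull.equations[:, 3]
    A, b = normalize_rows(A, b)
    return A, b, vertices[hull.vertices]


def min_margin(points: np.ndarray, A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Min slack of each point w.r.t. A x <= b (>0 strictly inside)."""
    points = np.atleast_2d(points)
    if A.size == 0:
        return np.full(len(points), np.inf)
    return (b[None, :] - points @ A.T).min(axis=1)
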