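"""Superimposed Voronoi complexes and intermediate-cell classification.

Morphing one skin into another rests on a structural fact about affine
ball interpolation: the power-diagram region of the interpolated ball
``b_ij(t)`` is ``v_i(source) ∩ v_j(target)`` for every t strictly between
0 and 1.  The arrangement obtained by intersecting every source Voronoi
cell with every target Voronoi cell — the superimposed complex — is
therefore the one fixed structure shared by all intermediate shapes.

Cells of the superimposed complex are classified by the dimension tuple
(dim v_X, dim v_Y, dim v_XY), ordered so the first entry is the larger:

* transversal cells satisfy dim v_XY = dim v_X + dim v_Y - 3 (the
  superimposition general position, SIGP); six tuple types exist;
* degenerate cells have dim v_XY > dim v_X + dim v_Y - 3; they arise in
  partial molecular movements where atoms coincide between source and
  target, and come in seven additional tuple types.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from ._polyhedra import Polyhedron, classify_polyhedron, realize_vertices
from .regular_triangulation import RegularComplex, classify_points
from .wp_algebra import BallSet, wp_interpolate

__all__ = [
    "IntermediateCell",
    "enumerate_tuple_taxonomy",
    "superimpose",
    "count_region_pairs",
    "region_pairs",
    "incident_region_pairs",
    "intermediate_delaunay_cell",
    "ResolutionError",
]


class ResolutionError(RuntimeError):
    """Sampling radius too coarse: region-pair count unstable under halving."""


@dataclass
class IntermediateCell:
    """A nonempty intersection v_X ∩ v_Y of source and target Voronoi cells."""

    X: tuple[int, ...]              # source ball indices
    Y: tuple[int, ...]              # target ball indices
    dims: tuple[int, int, int]      # (dim v_X, dim v_Y, dim v_XY), first >= second
    swapped: bool                   # True if source/target roles were swapped in dims
    regime: str                     # "transversal" (SIGP) or "degenerate"
    witness: np.ndarray             # relative-interior point of v_XY
    poly: Polyhedron
    vertices: np.ndarray

    @property
    def tuple_type(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def dim_intersection(self) -> int:
        return self.dims[2]

    @property
    def candidate_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i in self.X for j in self.Y]


_SINGLE_TYPES = [3, 2, 1, 0]


def enumerate_tuple_taxonomy(regime: str) -> list:
    """Analytic enumeration of intermediate Voronoi cell types.

    ``"single"`` (alias ``"tgp"``): the four Delaunay/Voronoi cell types
    of one complex in general position.  ``"transversal"`` (alias
    ``"sigp"``): tuples (a, b, c) with 3 >= a >= b >= c >= 0 and
    c = a + b - 3.  ``"degenerate"``: same range with c > a + b - 3.
    """
    key = regime.lower()
    if key in ("single", "tgp", "tgp_single"):
        return list(_SINGLE_TYPES)
    tuples = [
        (a, b, c)
        for a in range(3, -1, -1)
        for b in range(a, -1, -1)
        for c in range(b, -1, -1)
    ]
    if key in ("transversal", "sigp"):
        return [t for t in tuples if t[2] == t[0] + t[1] - 3]
    if key == "degenerate":
        return [t for t in tuples if t[2] > t[0] + t[1] - 3]
    raise ValueError(f"unknown regime {regime!r}")


def _tie_set(balls: BallSet, x: np.ndarray, tol: float = 1e-6) -> tuple[int, ...]:
    pd = balls.power_distances(x)
    return tuple(np.flatnonzero(pd <= pd.min() + tol))


def _aabb_overlap(va: np.ndarray, vb: np.ndarray, tol: float = 1e-6) -> bool:
    return bool(
        np.all(va.min(axis=0) <= vb.max(axis=0) + tol)
        and np.all(vb.min(axis=0) <= va.max(axis=0) + tol)
    )


def superimpose(source: RegularComplex, target: RegularComplex) -> list[IntermediateCell]:
    """All nonempty intersections v_X ∩ v_Y, classified and deduplicated.

    Each geometric cell is reported once under its canonical (maximal)
    label: the pair (X, Y) such that a relative-interior point of the
    intersection ties exactly on X in the source diagram and on Y in the
    target diagram.  Coincident features of partial movements are kept
    and classified as degenerate, never jittered away.
    """
    out: list[IntermediateCell] = []
    for cx in source.cells:
        for cy in target.cells:
            if not _aabb_overlap(cx.vertices, cy.vertices):
                continue
            A_ub = np.vstack([cx.poly.A_ub, cy.poly.A_ub])
            b_ub = np.concatenate([cx.poly.b_ub, cy.poly.b_ub])
            A_eq = np.vstack([cx.poly.A_eq, cy.poly.A_eq])
            b_eq = np.concatenate([cx.poly.b_eq, cy.poly.b_eq])
            poly = classify_polyhedron(A_ub, b_ub, A_eq, b_eq)
            if poly is None:
                continue
            if _tie_set(source.balls, poly.witness) != cx.balls:
                continue
            if _tie_set(target.balls, poly.witness) != cy.balls:
                continue
            a, b_, c = cx.voronoi_dim, cy.voronoi_dim, poly.dim
            swapped = b_ > a
            dims = (b_, a, c) if swapped else (a, b_, c)
            regime = "transversal" if c == dims[0] + dims[1] - 3 else "degenerate"
            verts = realize_vertices(poly)
            out.append(
                IntermediateCell(cx.balls, cy.balls, dims, swapped, regime, poly.witness, poly, verts)
            )
    return out


def census(cells: list[IntermediateCell]) -> dict[tuple[int, int, int], int]:
    """Tuple-type census of a superimposed complex."""
    out: dict[tuple[int, int, int], int] = {}
    for c in cells:
        out[c.dims] = out.get(c.dims, 0) + 1
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def region_pairs(
    locus: np.ndarray,
    radius: float,
    source: BallSet,
    target: BallSet,
    n_points: int = 20000,
) -> set[tuple[int, int]]:
    """Distinct (source-region, target-region) pairs on a sampling sphere."""
    pts = np.asarray(locus, float) + radius * _fibonacci_sphere(n_points)
    si = classify_points(pts, source)
    ti = classify_points(pts, target)
    return set(zip(si.tolist(), ti.tolist()))


def count_region_pairs(
    locus: np.ndarray,
    radius: float,
    source: BallSet,
    target: BallSet,
    n_points: int = 20000,
    check_stability: bool = True,
) -> int:
    """Number of distinct intermediate Voronoi regions incident to a locus.

    A dense deterministic Fibonacci-lattice sphere of the given radius is
    classified against both diagrams; the count must be stable under
    halving the radius, otherwise the radius was too coarse.
    """
    pairs = region_pairs(locus, radius, source, target, n_points)
    if check_stability:
        pairs_half = region_pairs(locus, radius / 2.0, source, target, n_points)
        if pairs != pairs_half:
            raise ResolutionError(
                f"region-pair set unstable under radius halving: "
                f"{len(pairs)} vs {len(pairs_half)}"
            )
    return len(pairs)


def _auto_radius(cell: IntermediateCell, scale: float) -> float:
    """Sampling radius: half the clearance to the nearest non-incident wall."""
    slack = cell.poly.b_ub - cell.poly.A_ub @ cell.witness
    clearance = float(slack.min()) if len(slack) else scale
    return max(min(clearance / 2.0, 0.05 * scale), 1e-6 * scale)


def incident_region_pairs(
    cell: IntermediateCell,
    source: BallSet,
    target: BallSet,
    radius: float | None = None,
    n_points: int = 20000,
) -> list[tuple[int, int]]:
    """The (i, j) region pairs whose closures contain the cell.

    Measured by sphere sampling around the cell's relative-interior
    witness; for transversal cells this equals the candidate product
    X x Y, for coincident (degenerate) cells it is a strict subset.
    """
    scale = float(np.linalg.norm(np.ptp(source.centers, axis=0))) + 1.0
    if radius is None:
        radius = _auto_radius(cell, scale)
    pairs = region_pairs(cell.witness, radius, source, target, n_points)
    pairs &= set(cell.candidate_pairs)
    return sorted(pairs)


def intermediate_delaunay_cell(
    cell: IntermediateCell,
    source: BallSet,
    target: BallSet,
    t: float,
    pairs: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Vertices of the dual intermediate Delaunay cell at time t.

    The convex hull of the interpolated ball centres of the incident
    (source, target) region pairs; e.g. a transversal face-edge crossing
    (2, 1, 0) has 2 x 3 incident pairs and the cell is a triangular prism.
    """
    if not 0.0 < t < 1.0:
        raise ValueError("t must lie strictly between 0 and 1")
    if pairs is None:
        pairs = incident_region_pairs(cell, source, target)
    centers = np.array(
        [wp_interpolate(source[i], target[j], t).center for i, j in pairs]
    )
    if len(centers) == 1:
        return centers
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(centers)
        return centers[hull.vertices]
    except QhullError:
        # lower-dimensional cell (segment / polygon): hull in its own chart
        d = centers - centers.mean(axis=0)
        _, s, vt = np.linalg.svd(d, full_matrices=False)
        rank = int(np.sum(s > 1e-9 * max(1.0, s[0])))
        if rank <= 1:
            lo, hi = np.argmin(d @ vt[0]), np.argmax(d @ vt[0])
            return centers[[lo, hi]] if lo != hi else centers[[lo]]
        proj = d @ vt[:rank].T
        hull = ConvexHull(proj)
        return centers[hull.vertices]
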