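"""Piecewise-quadric skin evaluation and mesh extraction.

Inside mixed cell mu_X with centre z_X, weight w_X, Delaunay direction
subspace E (dimension k) and Voronoi direction subspace V = E-perp, the
skin is the zero set of

    F_X(x) = ||P_V (x - z_X)||^2 - ||P_E (x - z_X)||^2 - w_X / 2

which is a sphere for k in {0, 3} and a hyperboloid of one or two sheets
(sign of w_X) for k in {1, 2}.  F_X is negative inside the skin body; the
per-cell values agree on shared mixed-cell facets, so the global field
F(x) = F_{cell of x}(x) is continuous and its zero set is the skin.

Meshing samples F on a regular grid, runs marching cubes, and then
Newton-projects every vertex onto the quadric of its mixed cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import marching_cubes

from ._polyhedra import min_margin
from .constants import MESH_PROJECT_TOL
from .mixed_complex import MixedCell

__all__ = [
    "QuadricPatch",
    "SkinMesh",
    "implicit_value",
    "implicit_gradient",
    "locate_mixed_cell",
    "skin_field",
    "mesh_skin",
    "project_to_patch",
]


@dataclass
class QuadricPatch:
    """Standard-form view of a mixed cell's quadric.

    In the local frame (origin ``z_X``, symmetry axis third) the patch is
    ``x1^2 + x2^2 + x3^2 = R^2`` (sphere) or ``x1^2 + x2^2 - x3^2 = +-R^2``
    (hyperboloid) with ``R^2 = |w_X| / 2``; ``sheet_sign`` is the +- of the
    hyperboloid form (one sheet when +, two sheets when -).
    """

    mixed_cell_id: int
    kind: str
    origin: np.ndarray
    axes: np.ndarray          # (3, 3) orthonormal rows; symmetry axis third
    R2: float
    sheet_sign: int

    @classmethod
    def from_cell(cls, cell: MixedCell) -> "QuadricPatch":
        E = cell.axes_delaunay
        k = E.shape[0]
        if k in (0, 3):
            axes = np.eye(3)
            kind = "sphere"
            sheet = 1
        else:
            kind = "hyperboloid"
            if k == 1:
                # Delaunay edge: symmetry axis along the edge
                axis = E[0]
            else:
                # Delaunay triangle: symmetry axis along the Voronoi edge
                # (the triangle's normal)
                axis = _complement(E)[0]
            u = _complement(axis[None, :])
            axes = np.vstack([u, axis[None, :]])
            # x1^2 + x2^2 - x3^2 = +-R^2:  + (one sheet) iff the quadric
            # opens around the symmetry axis, which happens when the
            # transverse directions are Voronoi directions (k == 1 dual)
            sheet = int(np.sign(cell.weight)) if k == 1 else int(-np.sign(cell.weight))
            if sheet == 0:
                sheet = 1
        return cls(cell.cell_id, kind, cell.center.copy(), axes, abs(cell.weight) / 2.0, sheet)


def _complement(rows: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the orthogonal complement of the row space."""
    if rows.size == 0:
        return np.eye(3)
    _, s, vt = np.linalg.svd(rows)
    rank = int(np.sum(s > 1e-10))
    return vt[rank:]


def implicit_value(x: np.ndarray, cell: MixedCell) -> np.ndarray | float:
    """F_X at one point or an (n, 3) array of points (negative inside)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    d = np.atleast_2d(x) - cell.center
    E = cell.axes_delaunay
    dd = np.einsum("ij,ij->i", d, d)
    if E.size:
        pe = d @ E.T
        ee = np.einsum("ij,ij->i", pe, pe)
    else:
        ee = np.zeros(len(d))
    val = (dd - ee) - ee - cell.weight / 2.0
    return float(val[0]) if single else val


def implicit_gradient(x: np.ndarray, cell: MixedCell) -> np.ndarray:
    """grad F_X = 2 (P_V - P_E)(x - z_X)."""
    x = np.asarray(x, dtype=float)
    d = np.atleast_2d(x) - cell.center
    E = cell.axes_delaunay
    pe = d @ E.T @ E if E.size else np.zeros_like(d)
    g = 2.0 * (d - 2.0 * pe)
    return g[0] if x.ndim == 1 else g


def cell_margins(points: np.ndarray, cells: list[MixedCell]) -> np.ndarray:
    """(n_points, n_cells) matrix of min half-space slacks."""
    points = np.atleast_2d(points)
    return np.column_stack([min_margin(points, c.A, c.b) for c in cells])


def locate_mixed_cell(
    x: np.ndarray, cells: list[MixedCell], tol: float = 1e-6
) -> int | np.ndarray:
    """Id of the mixed cell containing x (lowest id on boundary ties).

    Cells tile the domain, so the containing cell is the one with the
    largest minimum slack; a point outside every cell raises.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    M = cell_margins(np.atleast_2d(x), cells)
    # lowest id on ties: argmax picks the first maximal entry
    best = np.argmax(M > M.max(axis=1, keepdims=True) - tol, axis=1)
    if np.any(M[np.arange(len(M)), best] < -tol):
        raise ValueError("point outside the mixed-cell domain")
    ids = np.array([cells[i].cell_id for i in best])
    return int(ids[0]) if single else ids


def skin_field(points: np.ndarray, cells: list[MixedCell]) -> np.ndarray:
    """Global piecewise-quadric field F at an (n, 3) array of points."""
    points = np.atleast_2d(points)
    M = cell_margins(points, cells)
    which = np.argmax(M, axis=1)
    out = np.empty(len(points))
    for j, c in enumerate(cells):
        mask = which == j
        if mask.any():
            out[mask] = implicit_value(points[mask], c)
    return out


@dataclass
class SkinMesh:
    """Triangle mesh of a skin surface with per-vertex mixed-cell labels."""

    vertices: np.ndarray                  # (n, 3) float
    triangles: np.ndarray                 # (m, 3) int
    vertex_cell: np.ndarray               # (n,) mixed-cell id per vertex
    frame_t: float = 0.0
    vertex_ids: np.ndarray = field(default=None)  # stable correspondence ids

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        self.vertex_cell = np.asarray(self.vertex_cell, dtype=int).ravel()
        if self.vertex_ids is None:
            self.vertex_ids = np.arange(len(self.vertices))

    @property
    def is_empty(self) -> bool:
        return len(self.triangles) == 0

    def component_count(self) -> int:
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        n = len(self.vertices)
        if n == 0:
            return 0
        e = np.vstack([self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]])
        adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        return int(ncomp)

    def euler_characteristic(self) -> int:
        edges = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        return len(self.vertices) - len(edges) + len(self.triangles)

    def max_edge_triangle_count(self) -> int:
        edges = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        _, counts = np.unique(np.sort(edges, axis=1), axis=0, return_counts=True)
        return int(counts.max()) if len(counts) else 0


def _point_triangle_dist(points: np.ndarray, tri_v: np.ndarray) -> np.ndarray:
    """Min distance from each point to a triangle soup (exact, vectorised).

    ``tri_v`` has shape (m, 3, 3).  Classic closest-point-on-triangle
    via barycentric region tests, chunked over points.
    """
    a, b, c = tri_v[:, 0], tri_v[:, 1], tri_v[:, 2]
    ab, ac = b - a, c - a
    out = np.empty(len(points))
    chunk = max(1, int(2e6 // max(len(tri_v), 1)))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]                    # (n, 3)
        ap = p[:, None, :] - a[None, :, :]           # (n, m, 3)
        d1 = np.einsum("mk,nmk->nm", ab, ap)
        d2 = np.einsum("mk,nmk->nm", ac, ap)
        bp = p[:, None, :] - b[None, :, :]
        d3 = np.einsum("mk,nmk->nm", ab, bp)
        d4 = np.einsum("mk,nmk->nm", ac, bp)
        cp = p[:, None, :] - c[None, :, :]
        d5 = np.einsum("mk,nmk->nm", ab, cp)
        d6 = np.einsum("mk,nmk->nm", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom = va + vb + vc
        v = np.where(np.abs(denom) > 1e-30, vb / np.where(denom == 0, 1, denom), 0.0)
        w = np.where(np.abs(denom) > 1e-30, vc / np.where(denom == 0, 1, denom), 0.0)
        # clamp to the triangle region by region
        v_r = np.clip(v, 0.0, 1.0)
        w_r = np.clip(w, 0.0, 1.0)
        # vertex regions
        v_r = np.where((d1 <= 0) & (d2 <= 0), 0.0, v_r)
        w_r = np.where((d1 <= 0) & (d2 <= 0), 0.0, w_r)
        m_b = (d3 >= 0) & (d4 <= d3)
        v_r = np.where(m_b, 1.0, v_r)
        w_r = np.where(m_b, 0.0, w_r)
        m_c = (d6 >= 0) & (d5 <= d6)
        v_r = np.where(m_c, 0.0, v_r)
        w_r = np.where(m_c, 1.0, w_r)
        # edge AB
        m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        t_ab = d1 / np.where(d1 - d3 == 0, 1, d1 - d3)
        v_r = np.where(m_ab, t_ab, v_r)
        w_r = np.where(m_ab, 0.0, w_r)
        # edge AC
        m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        t_ac = d2 / np.where(d2 - d6 == 0, 1, d2 - d6)
        v_r = np.where(m_ac, 0.0, v_r)
        w_r = np.where(m_ac, t_ac, w_r)
        # edge BC
        m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        t_bc = (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1, (d4 - d3) + (d5 - d6))
        v_r = np.where(m_bc, 1.0 - t_bc, v_r)
        w_r = np.where(m_bc, t_bc, w_r)
        closest = (
            a[None, :, :]
            + v_r[:, :, None] * ab[None, :, :]
            + w_r[:, :, None] * ac[None, :, :]
        )
        diff = p[:, None, :] - closest
        out[s : s + chunk] = np.sqrt(np.einsum("nmk,nmk->nm", diff, diff).min(axis=1))
    return out


def mesh_hausdorff(a: "SkinMesh", b: "SkinMesh") -> float:
    """Symmetric Hausdorff distance between two triangle meshes.

    Measured vertex-to-surface in both directions with exact
    point-triangle distances, so it is insensitive to the two meshes'
    triangulations.
    """
    if a.is_empty and b.is_empty:
        return 0.0
    if a.is_empty or b.is_empty:
        return float("inf")
    d_ab = _point_triangle_dist(a.vertices, b.vertices[b.triangles])
    d_ba = _point_triangle_dist(b.vertices, a.vertices[a.triangles])
    return float(max(d_ab.max(), d_ba.max()))


def project_to_patch(
    x: np.ndarray,
    cell: MixedCell,
    tol: float = 1e-9,
    accept: float = MESH_PROJECT_TOL,
    max_iter: int = 30,
) -> np.ndarray | None:
    """Newton-project a point onto the cell's quadric; None on divergence.

    Iterates towards ``tol``; a point that only reaches ``accept`` is
    still considered on-surface (flat-gradient regions near a cone apex).
    """
    x = np.asarray(x, dtype=float).copy()
    for _ in range(max_iter):
        f = implicit_value(x, cell)
        if abs(f) <= tol:
            return x
        g = implicit_gradient(x, cell)
        gg = float(g @ g)
        if gg < 1e-18:
            break
        x = x - f * g / gg
    return x if abs(implicit_value(x, cell)) <= accept else None


def mesh_skin(
    cells: list[MixedCell],
    resolution: float,
    bounds: tuple[np.ndarray, np.ndarray],
    frame_t: float = 0.0,
) -> SkinMesh:
    """Extract the skin triangle mesh on a regular grid over ``bounds``.

    Marching cubes on the global field followed by per-vertex Newton
    projection onto the local quadric.  An empty zero set yields an empty
    mesh, not an error.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    ns = np.maximum(np.ceil((hi - lo) / resolution).astype(int) + 1, 4)
    axes = [np.linspace(lo[k], hi[k], ns[k]) for k in range(3)]
    spacing = [ax[1] - ax[0] for ax in axes]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    vol = skin_field(G, cells).reshape(ns)
    if vol.min() > 0 or vol.max() < 0:
        return SkinMesh(np.zeros((0, 3)), np.zeros((0, 3), int), np.zeros(0, int), frame_t)
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=spacing)
    verts = verts + lo
    ids = locate_mixed_cell(verts, cells)
    by_id = {c.cell_id: c for c in cells}
    keep = np.ones(len(verts), dtype=bool)
    for i in range(len(verts)):
        p = project_to_patch(verts[i], by_id[int(ids[i])])
        if p is None:
            keep[i] = False
        else:
            verts[i] = p
    if not keep.all():
        remap = -np.ones(len(verts), dtype=int)
        remap[keep] = np.arange(keep.sum())
        verts, ids = verts[keep], ids[keep]
        faces = remap[faces]
        faces = faces[(faces >= 0).all(axis=1)]
    return SkinMesh(verts, faces, ids, frame_t)
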