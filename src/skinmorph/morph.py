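"""Skin-to-skin morphing without per-frame diagram reconstruction.

The intermediate ball set is the many-to-many affine interpolation
``B(t) = {(1-t) b_i + t b_j}`` over all (source, target) ball pairs.  Its
power diagram is the superimposed Voronoi complex — one fixed structure
for every t in (0, 1) — so each intermediate cell keeps its identity for
the whole animation.  Per frame, the mixed-cell centre moves linearly in
t, the weight follows from the centre and a representative interpolated
ball, and every surface point is carried to the next frame by the local
translation plus the weight-ratio scaling

    p(t1) = z(t1) + (p(t0) - z(t0)) * sqrt(w(t1) / w(t0)).

Vertices that leave their mixed cell are re-located and re-projected;
cells whose patch appears mid-morph are locally re-sampled; vertices
whose patch disappears are retired.  Frame 0 is the source skin and the
final frame the target skin, each built from its own complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._polyhedra import hull_halfspaces, min_margin
from .constants import WEIGHT_FLOOR
from .mixed_complex import MixedCell, build_mixed_cells, mixed_cell_center, mixed_cell_weight
from .regular_triangulation import RegularComplex, build_regular_complex
from .skin_surface import SkinMesh, locate_mixed_cell, mesh_skin, project_to_patch
from .superimposition import IntermediateCell, incident_region_pairs, superimpose
from .wp_algebra import BallSet, WeightedPoint, wp_interpolate

__all__ = [
    "MorphConfig",
    "MorphState",
    "ReprojectionNeeded",
    "interpolate_ball_set",
    "interpolate_mixed_cell",
    "propagate_point",
    "generate_morph",
    "IntermediateStructure",
    "build_intermediate_structure",
]


class ReprojectionNeeded(RuntimeError):
    """Weight-ratio scaling is singular; the caller must re-project."""


@dataclass
class MorphConfig:
    """Animation parameters.

    ``t_schedule`` must start at 0, end at 1 and be strictly increasing;
    the default is ``frame_count`` uniform steps.
    """

    frame_count: int = 100
    t_schedule: np.ndarray | None = None
    mesh_resolution: float = 0.3
    seed: int = 0
    prune_redundant: bool = True

    def __post_init__(self) -> None:
        if self.frame_count < 2:
            raise ValueError("frame_count must be at least 2")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be positive")
        if self.t_schedule is None:
            self.t_schedule = np.linspace(0.0, 1.0, self.frame_count)
        else:
            self.t_schedule = np.asarray(self.t_schedule, dtype=float)
            self.frame_count = len(self.t_schedule)
        ts = self.t_schedule
        if ts[0] != 0.0 or ts[-1] != 1.0 or np.any(np.diff(ts) <= 0):
            raise ValueError("t_schedule must increase strictly from 0 to 1")


@dataclass
class MorphState:
    """One animation frame with its correspondence bookkeeping."""

    t: float
    balls: BallSet
    cells: list[MixedCell]
    mesh: SkinMesh
    retired: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    born: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def interpolate_ball_set(
    source: BallSet,
    target: BallSet,
    t: float,
    prune: bool = False,
    keep_pairs: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> BallSet:
    """The m x n interpolated ball set B(t) under many-to-many mapping.

    With ``prune`` on, pairs whose interpolated ball has an empty power
    cell at t = 0.5 are dropped for every t (valid because the
    intermediate diagram structure is constant on (0, 1)).
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("source and target ball sets must be non-empty")
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    pairs = keep_pairs
    if pairs is None:
        pairs = [(i, j) for i in range(len(source)) for j in range(len(target))]
        if prune:
            mid = _pair_ball_set(source, target, pairs, 0.5)
            rc = build_regular_complex(mid, seed=seed)
            redundant = set(rc.redundant_balls)
            pairs = [p for k, p in enumerate(pairs) if k not in redundant]
    return _pair_ball_set(source, target, pairs, t)


def _pair_ball_set(
    source: BallSet, target: BallSet, pairs: list[tuple[int, int]], t: float
) -> BallSet:
    pts = [wp_interpolate(source[i], target[j], t) for i, j in pairs]
    return BallSet.from_points(pts, labels=[f"{i}x{j}" for i, j in pairs])


def interpolate_mixed_cell(
    cell_source_center: np.ndarray,
    cell_target_center: np.ndarray,
    t: float,
    representative_ball_t: WeightedPoint,
) -> tuple[np.ndarray, float]:
    """Intermediate mixed-cell centre and weight at time t.

    The centre blends linearly between the matched source and target
    mixed-cell centres; the weight is the representative interpolated
    ball's weight minus its squared distance to the centre.
    """
    z = (1.0 - t) * np.asarray(cell_source_center, float) + t * np.asarray(
        cell_target_center, float
    )
    return z, mixed_cell_weight(z, representative_ball_t)


def propagate_point(
    p_t0: np.ndarray,
    z_t0: np.ndarray,
    w_t0: float,
    z_t1: np.ndarray,
    w_t1: float,
) -> np.ndarray:
    """Carry a surface point between frames by translation plus scaling.

    Raises :class:`ReprojectionNeeded` when the two weights differ in
    sign or the starting weight sits below the degeneracy floor (cone
    apex), in which case the caller re-projects onto the new patch.
    """
    if abs(w_t0) < WEIGHT_FLOOR or w_t0 * w_t1 <= 0.0:
        raise ReprojectionNeeded("weight sign change or degenerate cell weight")
    factor = float(np.sqrt(w_t1 / w_t0))
    return np.asarray(z_t1, float) + (np.asarray(p_t0, float) - np.asarray(z_t0, float)) * factor


# ---------------------------------------------------------------------------
# intermediate structure: the fixed superimposed complex, parameterised by t
# ---------------------------------------------------------------------------


@dataclass
class TrackedCell:
    """One superimposed cell with its linear-in-t mixed-cell model."""

    cell_id: int
    inter: IntermediateCell
    pairs: list[tuple[int, int]]          # incident (source, target) region pairs
    z_a: np.ndarray                       # scratch centres at the two reference times
    z_b: np.ndarray
    t_a: float
    t_b: float
    axes_delaunay: np.ndarray             # fixed: orthogonal complement of aff(v_XY)

    def center_at(self, t: float) -> np.ndarray:
        s = (t - self.t_a) / (self.t_b - self.t_a)
        return self.z_a + s * (self.z_b - self.z_a)

    def weight_at(self, t: float, source: BallSet, target: BallSet) -> float:
        i, j = self.pairs[0]
        rep = wp_interpolate(source[i], target[j], t)
        return mixed_cell_weight(self.center_at(t), rep)


@dataclass
class IntermediateStructure:
    source: BallSet
    target: BallSet
    rc_source: RegularComplex
    rc_target: RegularComplex
    inter_cells: list[IntermediateCell]
    tracked: list[TrackedCell]
    bounds: tuple[np.ndarray, np.ndarray]

    def mixed_cells_at(self, t: float) -> list[MixedCell]:
        cells = []
        for tc in self.tracked:
            z = tc.center_at(t)
            w = tc.weight_at(t, self.source, self.target)
            delta_verts = np.array(
                [wp_interpolate(self.source[i], self.target[j], t).center for i, j in tc.pairs]
            )
            A, b, verts = _minkowski_halved(delta_verts, tc.inter.vertices)
            cells.append(
                MixedCell(tc.cell_id, tuple(range(len(tc.pairs))), tc.inter.dim_intersection,
                          z, w, tc.axes_delaunay, A, b, verts)
            )
        return cells


def _minkowski_halved(dv: np.ndarray, vv: np.ndarray):
    pts = 0.5 * (dv[:, None, :] + vv[None, :, :]).reshape(-1, 3)
    # deduplicate (coincident interpolated centres in degenerate cells)
    pts = np.unique(np.round(pts, 9), axis=0)
    return hull_halfspaces(pts)


def scratch_center_weight(
    source: BallSet, target: BallSet, pairs: list[tuple[int, int]], t: float
) -> tuple[np.ndarray, float]:
    """Mixed-cell centre/weight computed from scratch on B(t).

    Solves the equal-power condition over the interpolated balls of the
    incident pairs directly at time t — no interpolation of centres — so
    it serves as the from-scratch oracle for the linear-in-t model.
    """
    bs = _pair_ball_set(source, target, pairs, t)
    # collapse duplicate balls (degenerate coincident pairs)
    uniq: list[int] = []
    seen: set[tuple] = set()
    for k in range(len(bs)):
        key = (tuple(np.round(bs.centers[k], 9)), round(float(bs.weights[k]), 9))
        if key not in seen:
            seen.add(key)
            uniq.append(k)
    sub = BallSet(bs.centers[uniq], bs.weights[uniq])
    X = tuple(range(len(sub)))
    z = mixed_cell_center(X, sub)
    w = mixed_cell_weight(z, sub[0])
    return z, w


def _delaunay_axes(inter: IntermediateCell) -> np.ndarray:
    """Fixed symmetry subspace: orthogonal complement of aff(v_XY)."""
    A = inter.poly.A_eq
    if A.size == 0:
        return np.zeros((0, 3))
    _, s, vt = np.linalg.svd(A)
    rank = int(np.sum(s > 1e-9 * max(1.0, s[0])))
    return vt[:rank]


def build_intermediate_structure(
    source: BallSet,
    target: BallSet,
    seed: int = 0,
    t_a: float = 0.3,
    t_b: float = 0.7,
    n_sample: int = 8192,
) -> IntermediateStructure:
    """Precompute the fixed superimposed complex and per-cell models."""
    rc0 = build_regular_complex(source, seed=seed)
    rc1 = build_regular_complex(target, seed=seed + 1)
    inter = superimpose(rc0, rc1)
    tracked: list[TrackedCell] = []
    for k, c in enumerate(inter):
        pairs = incident_region_pairs(c, source, target, n_points=n_sample)
        if not pairs:
            pairs = c.candidate_pairs
        z_a, _ = scratch_center_weight(source, target, pairs, t_a)
        z_b, _ = scratch_center_weight(source, target, pairs, t_b)
        tracked.append(TrackedCell(k, c, pairs, z_a, z_b, t_a, t_b, _delaunay_axes(c)))
    lo0, hi0 = source.bounding_box(source.max_radius + 1.0)
    lo1, hi1 = target.bounding_box(target.max_radius + 1.0)
    bounds = (np.minimum(lo0, lo1), np.maximum(hi0, hi1))
    return IntermediateStructure(source, target, rc0, rc1, inter, tracked, bounds)


# ---------------------------------------------------------------------------
# frame generation
# ---------------------------------------------------------------------------


def _static_mesh(balls: BallSet, resolution: float, seed: int, frame_t: float) -> tuple[SkinMesh, list[MixedCell]]:
    rc = build_regular_complex(balls, seed=seed)
    cells = build_mixed_cells(rc)
    lo, hi = balls.bounding_box(balls.max_radius + 2.0 * resolution + 0.5)
    mesh = mesh_skin(cells, resolution, (lo, hi), frame_t=frame_t)
    return mesh, cells

def _project_onto_field(
    verts: np.ndarray, cells: list[MixedCell]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locate + Newton-project points onto the skin at the current frame.

    Returns (projected points, cell ids, keep mask)."""
    from .skin_surface import cell_margins

    by_id = {c.cell_id: c for c in cells}
    M = cell_margins(verts, cells)
    raw = np.argmax(M, axis=1)
    inside = M[np.arange(len(verts)), raw] >= -1e-6
    ids = np.array([cells[k].cell_id for k in raw])
    out = verts.copy()
    keep = inside.copy()
    for i in np.flatnonzero(inside):
        # project / relocate to a fixed point: a vertex is kept only when
        # it lies on the quadric of the cell that actually contains it
        # (guards against phantom zero sets outside a cell's polytope)
        cid = int(ids[i])
        p = verts[i]
        ok = False
        for _ in range(5):
            c = by_id[cid]
            p_new = project_to_patch(p, c)
            if p_new is None:
                break
            p = p_new
            try:
                cid_new = int(locate_mixed_cell(p, cells))
            except ValueError:
                break
            if cid_new == cid:
                ok = True
                break
            cid = cid_new
        if ok:
            out[i], ids[i] = p, cid
        else:
            keep[i] = False
    return out, ids, keep


def _resample_cell(
    cell: MixedCell, cells: list[MixedCell], resolution: float, frame_t: float
) -> SkinMesh:
    """Local marching cubes over one cell's bounding box (patch birth)."""
    lo = cell.vertices.min(axis=0) - resolution
    hi = cell.vertices.max(axis=0) + resolution
    local = mesh_skin(cells, resolution, (lo, hi), frame_t=frame_t)
    if local.is_empty:
        return local
    in_cell = local.vertex_cell == cell.cell_id
    # keep triangles touching the cell (overlap the neighbours slightly so
    # the seam between resampled and propagated regions has no gap)
    tri_keep = in_cell[local.triangles].any(axis=1)
    used = np.zeros(len(local.vertices), dtype=bool)
    used[np.unique(local.triangles[tri_keep])] = True
    remap = -np.ones(len(local.vertices), dtype=int)
    remap[used] = np.arange(used.sum())
    tris = remap[local.triangles[tri_keep]]
    return SkinMesh(local.vertices[used], tris, local.vertex_cell[used], frame_t)


def _surface_samples(cell: MixedCell, t: float, n_extra: int | None = None) -> np.ndarray:
    """Deterministic samples of the patch inside the cell polytope.

    Probes (polytope vertices, centroid, midpoints, a few fixed random
    convex combinations) are Newton-projected onto the quadric; those
    landing inside the polytope witness where the patch actually lives.
    """
    V = cell.vertices
    centroid = V.mean(axis=0)
    probes = [V, centroid[None, :], 0.5 * (V + centroid), cell.center[None, :]]
    rng = np.random.default_rng((cell.cell_id * 1000003 + int(round(t * 1e6))) % 2**31)
    if n_extra is None:
        n_extra = max(16, 4 * len(V))
    lam = rng.dirichlet(np.ones(len(V)), size=n_extra)
    probes.append(lam @ V)
    samples = []
    for p in np.vstack(probes):
        q = project_to_patch(p, cell)
        if q is not None and min_margin(q[None], cell.A, cell.b)[0] >= -1e-6:
            samples.append(q)
    return np.array(samples) if samples else np.zeros((0, 3))


def generate_morph(
    source: BallSet, target: BallSet, cfg: MorphConfig | None = None
) -> list[MorphState]:
    """Full morph: source skin -> interpolated frames -> target skin.

    Frame 0 and the final frame are built from the source and target
    complexes; interior frames share the fixed superimposed complex and
    are produced by propagation with local repair.  Vertex ids are stable
    across interior frames; retirements and births are recorded per
    frame (the two endpoint hand-offs retire/bear all ids).
    """
    cfg = cfg or MorphConfig()
    res = cfg.mesh_resolution
    struct = build_intermediate_structure(source, target, seed=cfg.seed)
    states: list[MorphState] = []

    mesh0, cells0 = _static_mesh(source, res, cfg.seed, 0.0)
    states.append(MorphState(0.0, source, cells0, mesh0))

    next_id = int(mesh0.vertex_ids.max()) + 1 if len(mesh0.vertex_ids) else 0
    prev_cells: list[MixedCell] | None = None
    prev_mesh: SkinMesh | None = None

    for t in cfg.t_schedule[1:-1]:
        t = float(t)
        cells_t = struct.mixed_cells_at(t)
        region_pairs = sorted(
            {p for tc in struct.tracked if tc.inter.dims == (3, 3, 3) for p in tc.pairs}
        )
        balls_t = _pair_ball_set(source, target, region_pairs, t)
        if prev_mesh is None:
            # hand-off from the source mesh: project its vertices onto skin(B(t))
            verts, ids, keep = _project_onto_field(mesh0.vertices, cells_t)
            vids = mesh0.vertex_ids.copy()
        else:
            by_prev = {c.cell_id: c for c in prev_cells}
            by_cur = {c.cell_id: c for c in cells_t}
            verts = prev_mesh.vertices.copy()
            for i in range(len(verts)):
                c0 = by_prev[int(prev_mesh.vertex_cell[i])]
                c1 = by_cur[c0.cell_id]
                try:
                    verts[i] = propagate_point(verts[i], c0.center, c0.weight, c1.center, c1.weight)
                except ReprojectionNeeded:
                    pass  # keep the old position; projection below repairs it
            verts, ids, keep = _project_onto_field(verts, cells_t)
            vids = prev_mesh.vertex_ids.copy()

        base = prev_mesh if prev_mesh is not None else mesh0

        # local repair: re-sample any cell whose realised patch region is
        # not covered by its propagated vertices (patch birth or growth)
        resample: list[MixedCell] = []
        for c in cells_t:
            samples = _surface_samples(c, t)
            if len(samples) == 0:
                continue
            owned = verts[keep & (ids == c.cell_id)]
            if len(owned) == 0:
                resample.append(c)
                continue
            d2 = ((samples[:, None, :] - owned[None, :, :]) ** 2).sum(axis=2)
            if np.sqrt(d2.min(axis=1)).max() > 1.5 * res:
                resample.append(c)
        resample_ids = {c.cell_id for c in resample}
        # triangles losing a vertex to retirement leave one-ring holes:
        # re-sample every cell such a triangle touches
        dropped = ~keep[base.triangles].all(axis=1)
        if dropped.any():
            touched = np.unique(base.triangles[dropped])
            resample_ids |= set(ids[touched][keep[touched]].tolist())
            by_cid = {c.cell_id: c for c in cells_t}
            resample = [by_cid[cid] for cid in sorted(resample_ids)]
        if resample_ids:
            keep = keep & ~np.isin(ids, list(resample_ids))

        retired = vids[~keep]
        remap = -np.ones(len(verts), dtype=int)
        remap[keep] = np.arange(keep.sum())
        tris = remap[base.triangles]
        tris = tris[(tris >= 0).all(axis=1)]
        verts, ids, vids = verts[keep], ids[keep], vids[keep]

        born_ids: list[int] = []
        add_v, add_t, add_c = [], [], []
        for c in resample:
            local = _resample_cell(c, cells_t, res, t)
            if local.is_empty:
                continue
            off = len(verts) + sum(len(v) for v in add_v)
            add_v.append(local.vertices)
            add_t.append(local.triangles + off)
            add_c.append(local.vertex_cell)
            born_ids.extend(range(next_id, next_id + len(local.vertices)))
            next_id += len(local.vertices)
        if add_v:
            verts = np.vstack([verts] + add_v)
            tris = np.vstack([tris] + add_t) if len(tris) else np.vstack(add_t)
            ids = np.concatenate([ids] + add_c)
            vids = np.concatenate([vids, np.array(born_ids, dtype=int)])

        mesh_t = SkinMesh(verts, tris, ids, frame_t=t, vertex_ids=vids)
        states.append(
            MorphState(t, balls_t, cells_t, mesh_t,
                       retired=np.asarray(retired, dtype=int),
                       born=np.asarray(born_ids, dtype=int))
        )
        prev_cells, prev_mesh = cells_t, mesh_t

    mesh1, cells1 = _static_mesh(target, res, cfg.seed + 1, 1.0)
    mesh1.vertex_ids = np.arange(next_id, next_id + len(mesh1.vertices))
    last_ids = states[-1].mesh.vertex_ids if len(states) > 1 else mesh0.vertex_ids
    states.append(
        MorphState(1.0, target, cells1, mesh1,
                   retired=np.asarray(last_ids, dtype=int),
                   born=mesh1.vertex_ids.copy())
    )
    return states
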