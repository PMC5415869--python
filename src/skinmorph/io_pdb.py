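"""PDB input, mesh output, and constructed degenerate fixtures.

Atoms are read from fixed-column PDB files (via gemmi) into ball sets
whose weights are squared van der Waals radii; meshes and per-vertex
correspondence records are written as plain OBJ/PLY and text files.

``make_degenerate_fixture`` builds small source/target ball-set pairs
whose superimposed Voronoi complex realises, by construction, any one of
the thirteen intermediate cell tuple types (six transversal, seven
degenerate), together with a witness locus on the cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .skin_surface import SkinMesh
from .wp_algebra import BallSet

__all__ = [
    "RadiusTable",
    "BONDI",
    "read_pdb",
    "write_frame_mesh",
    "read_mesh",
    "write_correspondence",
    "make_degenerate_fixture",
    "FIXTURE_KINDS",
]

#: Bondi van der Waals radii (Angstrom)
BONDI: dict[str, float] = {
    "H": 1.20, "HE": 1.40, "LI": 1.82, "BE": 1.53, "B": 1.92, "C": 1.70,
    "N": 1.55, "O": 1.52, "F": 1.47, "NE": 1.54, "NA": 2.27, "MG": 1.73,
    "AL": 1.84, "SI": 2.10, "P": 1.80, "S": 1.80, "CL": 1.75, "AR": 1.88,
    "K": 2.75, "CA": 2.31, "NI": 1.63, "CU": 1.40, "ZN": 1.39, "GA": 1.87,
    "AS": 1.85, "SE": 1.90, "BR": 1.85, "KR": 2.02, "AG": 1.72, "CD": 1.58,
    "I": 1.98, "XE": 2.16, "PT": 1.75, "AU": 1.66, "HG": 1.55, "PB": 2.02,
    "FE": 1.94, "MN": 1.94, "CO": 1.92, "U": 1.86,
}


@dataclass
class RadiusTable:
    """Element -> van der Waals radius with an optional fallback.

    The default is the Bondi set with a 1.5 A fallback for elements the
    table does not list (a warning is emitted per unknown element).
    """

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI))
    fallback: float | None = 1.5
    name: str = "bondi"

    def lookup(self, element: str, context: str = "") -> float:
        r = self.radii.get(element.upper().strip())
        if r is not None:
            return r
        if self.fallback is None:
            raise ValueError(
                f"unknown element {element!r} and no fallback radius"
                + (f" ({context})" if context else "")
            )
        warnings.warn(
            f"unknown element {element!r}{' at ' + context if context else ''}; "
            f"using fallback radius {self.fallback} A",
            stacklevel=2,
        )
        return self.fallback


def read_pdb(
    path,
    radius_table: RadiusTable | None = None,
    include_waters: bool = False,
) -> BallSet:
    """Parse ATOM/HETATM records of a PDB file into a ball set.

    One ball per accepted atom of the first model: centre = coordinates
    in the PDB frame, weight = (vdW radius)^2.  Alternate locations other
    than blank or 'A' are skipped; waters are excluded unless requested.
    Labels carry ``serial:element:chain:resname:seq[icode]``.
    """
    import gemmi

    table = radius_table or RadiusTable()
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    centers, weights, labels = [], [], []
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for residue in chain:
                if not include_waters and residue.is_water():
                    continue
                for atom in residue:
                    if atom.altloc not in ("\0", "", "A"):
                        continue
                    elem = atom.element.name
                    label = (
                        f"{atom.serial}:{elem}:{chain.name}:{residue.name}:"
                        f"{residue.seqid.num}{residue.seqid.icode.strip()}"
                    )
                    r = table.lookup(elem, context=f"{path.name} serial {atom.serial}")
                    centers.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    weights.append(r * r)
                    labels.append(label)
    if not centers:
        raise ValueError(f"no parseable ATOM/HETATM records in {path}")
    return BallSet(np.array(centers), np.array(weights), labels)


def write_frame_mesh(mesh: SkinMesh, path, format: str | None = None) -> Path:
    """Write a skin mesh as OBJ or PLY (ascii), preserving vertex order."""
    import trimesh

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in ("OBJ", "PLY"):
        raise ValueError(f"unsupported mesh format {fmt!r}")
    if mesh.is_empty:
        raise ValueError("refusing to write an empty mesh")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    if fmt == "OBJ":
        path.write_text(trimesh.exchange.obj.export_obj(tm, include_normals=False))
    else:
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        path.write_bytes(data)
    return path


def read_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    """Read back vertices and faces of an OBJ/PLY file (round-trip check)."""
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    return np.asarray(tm.vertices, float), np.asarray(tm.faces, int)


def write_correspondence(mesh: SkinMesh, path) -> Path:
    """Per-vertex correspondence record: vertex_id  mixed_cell_id  t."""
    path = Path(path)
    lines = [
        f"{int(vid)}\t{int(cid)}\t{mesh.frame_t:.10g}"
        for vid, cid in zip(mesh.vertex_ids, mesh.vertex_cell)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def random_ball_set(
    n: int,
    seed: int,
    spread: float = 1.0,
    weight_range: tuple[float, float] = (2.25, 3.6),
    min_separation: float = 1.2,
    offset: np.ndarray | None = None,
) -> BallSet:
    """Generic random ball set emulating a small molecule fragment.

    Centres are drawn in a compact cluster with a minimum pairwise
    separation (rejection sampling) and weights in the squared-vdW-radius
    range of common elements, so unions overlap the way covalently bonded
    atoms do and the skin stays connected-ish rather than evaporating.
    """
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    while len(centers) < n:
        c = rng.normal(scale=spread, size=3)
        if all(np.linalg.norm(c - z) >= min_separation for z in centers):
            centers.append(c)
    centers_arr = np.array(centers)
    if offset is not None:
        centers_arr = centers_arr + np.asarray(offset, float)
    weights = rng.uniform(*weight_range, size=n)
    return BallSet(centers_arr, weights)


# ---------------------------------------------------------------------------
# constructed degenerate fixtures
# ---------------------------------------------------------------------------


def _pair(axis: np.ndarray, sep: float = 1.0, shift: float = 0.0, w: float = 1.0) -> BallSet:
    """Two equal balls straddling the plane <axis, x> = shift."""
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    c = shift * axis
    return BallSet(np.array([c - sep * axis, c + sep * axis]), np.array([w, w]))


def _trio(
    axis: np.ndarray, rho: float = 1.4, phase_deg: float = 0.0, w: float = 1.0
) -> BallSet:
    """Three equal balls around ``axis``; their common Voronoi edge IS the axis."""
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    # orthonormal frame (u, v, axis)
    tmp = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, tmp)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    ang = np.deg2rad(phase_deg) + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    centers = rho * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)
    return BallSet(centers, np.full(3, w))


def _trio_at_angles(angles_deg, rho: float = 1.4, w: float = 1.0) -> BallSet:
    """Three equal balls in the z=0 plane at given polar angles (edge = z-axis)."""
    ang = np.deg2rad(np.asarray(angles_deg, float))
    centers = rho * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(len(ang))])
    return BallSet(centers, np.full(len(ang), w))


def _tetra(scale: float = 1.5, w: float = 1.0, rot_z_deg: float = 0.0) -> BallSet:
    """Four equal balls on a regular tetrahedron centred at the origin."""
    T = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    T = T / np.sqrt(3.0) * scale
    if rot_z_deg:
        a = np.deg2rad(rot_z_deg)
        R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        T = T @ R.T
    return BallSet(T, np.full(4, w))


def _rotate_z(balls: BallSet, deg: float) -> BallSet:
    a = np.deg2rad(deg)
    R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    return BallSet(balls.centers @ R.T, balls.weights.copy())


_EX, _EY, _EZ = np.eye(3)

FIXTURE_KINDS: tuple[tuple[int, int, int], ...] = (
    (3, 3, 3), (3, 2, 2), (3, 1, 1), (3, 0, 0), (2, 2, 1), (2, 1, 0),
    (2, 2, 2), (2, 1, 1), (2, 0, 0), (1, 1, 1), (1, 1, 0), (1, 0, 0), (0, 0, 0),
)


def make_degenerate_fixture(
    kind: tuple[int, int, int], variant: str = "default"
) -> tuple[BallSet, BallSet, np.ndarray]:
    """Source/target ball sets realising one intermediate-cell tuple type.

    Returns (source, target, locus) where the locus is a point on (or
    nearest to) the cell of the requested type in the superimposed
    complex.  The six transversal kinds are generic crossings; the seven
    degenerate kinds encode partial-movement coincidences (shared planes,
    overlapping edges, coincident vertices).

    For kind (1, 1, 1) the default variant uses identical trios (minimal
    surrounding-region count); ``variant="rotated"`` rotates the target
    trio by 30 degrees about the common edge, the maximal case.
    """
    kind = tuple(int(k) for k in kind)
    origin = np.zeros(3)
    if kind == (3, 3, 3):
        return _pair(_EX), _pair(_EY), np.array([-2.0, -2.0, 0.0])
    if kind == (3, 2, 2):
        return _pair(_EX, shift=0.4), _pair(_EY), np.array([-1.0, 0.0, 0.0])
    if kind == (3, 1, 1):
        return _pair(_EX, shift=0.5), _trio(_EZ, phase_deg=12.3), origin
    if kind == (3, 0, 0):
        return _pair(_EX, shift=0.7), _tetra(rot_z_deg=9.0), origin
    if kind == (2, 2, 1):
        return _pair(_EX), _pair(_EY), origin
    if kind == (2, 1, 0):
        return _pair(_EX), _trio(_EX, phase_deg=21.0), origin
    if kind == (2, 2, 2):
        return _pair(_EX, sep=1.0), _pair(_EX, sep=2.0), origin
    if kind == (2, 1, 1):
        # one target wedge boundary lies inside the source face plane
        return _pair(_EX), _trio_at_angles([0.0, 90.0, 180.0]), origin
    if kind == (2, 0, 0):
        return _pair(_EX), _tetra(rot_z_deg=13.0), origin
    if kind == (1, 1, 1):
        src = _trio(_EZ, phase_deg=7.0)
        tgt = src if variant == "default" else _rotate_z(src, 30.0)
        return src, BallSet(tgt.centers.copy(), tgt.weights.copy()), origin
    if kind == (1, 1, 0):
        # phases chosen so every source wedge meets every target wedge:
        # the crossing vertex is surrounded by the full 3 x 3 = 9 regions
        return _trio(_EZ, rho=1.4, phase_deg=10.0), _trio(_EX, rho=1.0, phase_deg=30.0), origin
    if kind == (1, 0, 0):
        return _trio(_EZ, phase_deg=31.0), _tetra(rot_z_deg=17.0), origin
    if kind == (0, 0, 0):
        src = _tetra()
        return src, _tetra(rot_z_deg=40.0), origin
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
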