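# Methods

This note records the model, the numerical choices, and the limits of
what the test suite demonstrates.

## Geometry model

**Ball algebra.** Atoms are weighted points (z, w), w = r² in Å² with r
the van der Waals radius (Bondi set; 1.5 Å fallback for unlisted
elements, with a warning). Weights may be negative end-to-end; a
negative-weight ball is an imaginary sphere that still shapes the power
diagram. The square-root shrink is fixed at w → w/2; no user-facing
shrink factor is exposed.

**Regular triangulation.** Built by the classical lifting map
(z, w) → (z, ‖z‖² − w) ∈ ℝ⁴; lower convex-hull facets (scipy/Qhull) are
the tetrahedra, and every lower-dimensional cell is a face of one.
Inputs with fewer than five balls are enumerated subset-by-subset with
LP emptiness tests instead — the same route doubles as an independent
oracle in the tests. Each cell's power cell is stored in constraint
form (equal-power equalities within X, domination inequalities against
all other balls) and realised inside a clipping box.

*Canonical merging.* A relative-interior witness of each candidate cell
is classified against all balls; if it ties on a strictly larger set X*
(cospherical degeneracy), the cell is registered once under X* as a
non-simplicial cell. This is essential for interpolated ball sets,
whose diagrams violate the simplicial general-position assumption by
construction (six or more balls share one power vertex wherever a
source face crosses a target edge). When Qhull itself rejects a
degenerate input, a deterministic jitter of 1e-8 Å (seeded) perturbs
the *candidate discovery only*; classification always runs against the
exact coordinates, so coincident features are merged, never slivered.

*Clipping box.* Unbounded power cells are clipped to a box padded by
(diameter + 3·r_max + 4) Å around the centres, then expanded to contain
every bounded tetrahedron power vertex (capped at 100× the box
diagonal). The expansion matters: a sliver tetrahedron's power vertex
can sit far outside any fixed-pad box, and dropping its cell would
punch a hole in the mixed-cell tiling. Cells whose power vertex lies
beyond the cap are omitted; their mixed cells sit at least half the cap
away from the molecule, far outside any meshing domain.

**Mixed cells and the skin field.** The mixed cell is the half-scaled
Minkowski sum of the Delaunay cell (convex hull of centres) and the
realised power cell, stored as a half-space list via a convex hull of
pairwise midpoints. The skin is the zero set of the per-cell quadric

F_X(x) = ‖P_V(x − z_X)‖² − ‖P_E(x − z_X)‖² − w_X/2,

negative inside the body. The same formula covers all four cell types;
its values agree on shared facets (asserted to 1e-6 on sampled facet
points), so the global field is continuous and no per-patch sign fixing
is needed. Degenerate w_X = 0 yields a cone; vertices at the apex fail
the gradient test and are retired rather than perturbed.

**Meshing.** F is sampled on a uniform grid (default 0.3 Å; tests use
0.15–0.35 Å) over the centre extent padded by r_max plus a margin,
marching cubes extracts the zero surface, and each vertex is
Newton-projected onto the quadric of its mixed cell (target residual
1e-9, accepted up to 1e-6). One meshing strategy only; no guaranteed
triangle quality, no adaptive refinement.

## Superimposition

Intermediate cells are all nonempty intersections v_X ∩ v_Y of source
and target power cells, computed by stacking the two constraint systems
and classifying the result with LPs: feasibility, implicit-equality
detection (per-row slack maximisation when the Chebyshev radius in the
affine hull falls below 1e-7), affine rank by SVD. Each geometric cell
is reported once under its canonical label (the tie sets of a
relative-interior witness in both diagrams). Dimension tuples with
dim v_XY = dim v_X + dim v_Y − 3 are transversal; larger intersections
are degenerate. Coincident features of partial movements are detected
by this exact arithmetic and never jittered away — the degenerate
taxonomy exists precisely to describe them.

Incident region pairs at a cell are *measured*, not inferred from the
label product: a Fibonacci-lattice sphere (2·10⁴ points) around the
witness is classified against both diagrams and the distinct
(source, target) pairs are counted. The sampling radius is half the
witness's clearance to the nearest non-incident wall, and every count
must be stable under halving the radius, else an error is raised. For
transversal cells the measured set equals X × Y; for coincident cells
it is a strict subset (e.g. three pairs, not nine, around an overlap
edge shared by identical trios).

## Morphing engine

The superimposed complex is computed once. For each intermediate cell,
the mixed-cell centre is solved from scratch (equal-power least squares
over the incident interpolated balls) at t = 0.3 and t = 0.7, and the
two solutions define a linear-in-t model; the weight at any t follows
from the centre and one representative interpolated ball. The linearity
is a property of the product structure of superimposed cells, and the
tests verify it against from-scratch solves at t ∈ {0.25, 0.5, 0.75} to
1e-7. The reference times 0.3/0.7 are arbitrary interior points; any
two would give the same line.

Frames: frame 0 and the final frame are meshed from the source and
target complexes directly. The first interior frame projects the source
mesh's vertices onto the intermediate field (the hand-off); subsequent
frames propagate each vertex by the translation-plus-scaling rule, then
re-locate and Newton-project it (a vertex that slides across a cell
facet is projected again in its new cell, to a fixed point, at most 5
rounds). Propagation is skipped in favour of direct re-projection when
the weights change sign or |w(t₀)| < 1e-8 Å².

Local repair per frame: deterministic probes in every cell polytope are
projected onto the cell's quadric; if a cell's realised patch region
has a surface sample farther than 1.5× the mesh resolution from all of
the cell's propagated vertices (patch birth or growth), the cell is
re-sampled by local marching cubes, retiring its old vertices and
recording births. Cells touched by triangles that lost a vertex to
retirement are re-sampled as well, so retirement never leaves one-ring
holes. Re-sampled local meshes keep boundary-crossing triangles, so
seams overlap rather than gap. Vertex ids are stable across interior
frames; the endpoint hand-offs retire and bear all ids by construction.

Redundant interpolated pairs (empty power cell at t = 0.5) may be
pruned once for all t, justified by the t-invariance of the
superimposed diagram; the tests confirm pruned and unpruned runs give
the same mesh to within the resolution.

## Synthetic data

`random_ball_set` emulates a small molecule fragment: centres in a
compact Gaussian cluster (scale 1 Å) with a 1.2 Å minimum pairwise
separation by rejection, weights uniform in [2.25, 3.6] Å² (vdW radii
1.5–1.9 Å). Morph test pairs offset the target cluster by ~0.6 Å so
source and target overlap the way roughly superposed conformers do.
What it does not emulate: covalent bond-length regularity, element
composition, secondary structure, or molecule-scale atom counts —
passing tests show the geometry and the propagation machinery are
correct at fragment scale, not that frame rates or mesh quality hold at
protein scale. Morphs between *distant* fragments can pass through
legitimately empty intermediate skins (the affine weight deficit
t(1−t)‖Δz‖² turns every interpolated ball imaginary); the generator's
defaults avoid this regime, and the meshers treat an empty zero set as
an empty mesh, not an error.

The thirteen degenerate fixtures are hand-built: trios of equal balls
around an axis realise Voronoi edges, pairs realise faces, regular
tetrahedra realise vertices, and combinations (shifted, rotated, or
shared between source and target) realise each dimension tuple. The
edge-edge crossing fixture's trio phases (10° and 30°) are chosen so
every source wedge meets every target wedge, realising the full nine
surrounding regions; other phase choices realise eight, which is a
different (valid) geometry but not the canonical maximal one.

## Tolerances

| quantity | value | where |
|---|---|---|
| scalar comparisons (Å²) | 1e-9 | ball algebra, weights |
| affine rank / cell dimension | 1e-7 | LP classification, SVD |
| candidate-discovery jitter | 1e-8 Å | degenerate hulls only |
| Newton projection target / acceptance | 1e-9 / 1e-6 | meshing, propagation |
| propagation weight floor | 1e-8 Å² | cone-apex guard |
| equal-power tie detection | 1e-6 | canonical labels |

## Known limitations

* Vertices reassigned across a mixed-cell facet during the hand-off
  move by the square of their distance to the facet (two quadrics meet
  C¹ there); stationary morphs therefore show a one-time drift of up to
  ~1e-5 Å rather than exact fixity.
* The alternative vertex counts of the degenerate Delaunay cells
  (quadrangle vs pentagon, hexahedron vs heptahedron, …) are realised
  by one fixture each; the geometric condition selecting each
  alternative is not enumerated.
* Mesh connectivity across a re-sampled cell boundary is overlapped,
  not stitched; downstream consumers needing watertight meshes should
  re-mesh frames.
* The morph is geometric interpolation of balls, not molecular
  dynamics; trajectories have no physical meaning.
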