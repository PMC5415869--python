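# skinmorph

Molecular skin surfaces and continuous skin-to-skin morphing for
structural bioinformatics.

A molecule is a union of balls: one ball per atom, centred at the atomic
coordinates with the van der Waals radius. The **molecular skin surface**
of a ball set *B* is the boundary of the union of all *square-root
shrunken* balls drawn from conv(*B*) in ball algebra — a C²-smooth,
self-intersection-free surface that decomposes into sphere and
hyperboloid patches, one per *mixed cell* of the weighted Delaunay /
power-diagram pair of *B*. `skinmorph` builds these surfaces from PDB
files or explicit ball lists, and morphs one skin into another without
rebuilding the underlying diagrams for every animation frame.

## The model

A ball is a weighted point *b* = (*z*, *w*) with centre *z* ∈ ℝ³ and
weight *w* (radius², possibly negative). The power distance of a point
*x* from *b* is π_b(*x*) = ‖*x* − *z*‖² − *w*. Ball algebra closes the
set under affine combination:

    b_i + b_j = (z_i + z_j,  w_i + w_j + 2⟨z_i, z_j⟩)
    γ b_i     = (γ z_i,      γ w_i + (γ² − γ)‖z_i‖²)
    √b        = (z, w/2)

so that (1−t) b_i + t b_j is again a ball whose weight dips below the
linear blend by exactly t(1−t)‖z_i − z_j‖². The skin of *B* is
∂⋃ √conv(*B*). Inside the mixed cell μ_X = (δ_X + v_X)/2 — the
half-scaled Minkowski sum of a Delaunay cell and its dual power cell —
the skin is the quadric

    ‖P_V (x − z_X)‖² − ‖P_E (x − z_X)‖² = w_X / 2

where z_X = aff(δ_X) ∩ aff(v_X), w_X = w_i − ‖z_X − z_i‖² for any ball
*i* of X, and P_E, P_V project onto the Delaunay and Voronoi direction
subspaces: a sphere when dim δ_X ∈ {0, 3}, a hyperboloid otherwise.

**Morphing.** For a source set of *m* balls and a target set of *n*
balls, the intermediate set is the many-to-many interpolation
B(t) = {(1−t) b_i + t b_j}. Its power diagram is *independent of t* on
(0, 1): the region of the pair (i, j) is v_i(source) ∩ v_j(target), so
the superimposed Voronoi complex is one fixed structure for the entire
animation. Intermediate mixed-cell centres move linearly in t, weights
follow from the centre, and each surface point is carried frame to frame
by the local translation plus the weight-ratio scaling
p(t₁) = z(t₁) + (p(t₀) − z(t₀))·√(w(t₁)/w(t₀)), giving per-vertex
correspondence across frames for free.

Superimposed cells are classified by the dimension tuple
(dim v_X, dim v_Y, dim v_XY). Six *transversal* types satisfy
dim v_XY = dim v_X + dim v_Y − 3; seven additional *degenerate* types
arise in partial molecular movements, where atoms shared by source and
target force coincident Voronoi features. `skinmorph` keeps those
coincidences exact (no jitter) and classifies them explicitly.

## Worked example

Build the skin of a single carbon atom (vdW radius 1.70 Å):

```bash
$ skinmorph build single.pdb -o carbon.obj --resolution 0.2
{
  "input": "single.pdb",
  "n_atoms": 1,
  "n_mixed_cells": 1,
  "redundant_balls": [],
  "jitter_applied": false,
  "n_vertices": 678,
  "n_triangles": 1352
}
```

Every mesh vertex lies at radius 1.70/√2 ≈ 1.202 Å from the atom: the
skin of a single ball is the ball shrunk by √2.

Morph a two-atom fragment into a three-atom fragment:

```bash
$ skinmorph morph two.pdb three.pdb -o demo --frames 5 --resolution 0.3
{
  "source": "two.pdb",
  "target": "three.pdb",
  "m": 2,
  "n": 3,
  "m_x_n": 6,
  "frames_written": 5,
  "retired_vertices": 638
}
```

`m_x_n = 6` is the interpolated ball count (many-to-many mapping).
`demo/` receives one OBJ mesh and one correspondence file per frame;
each correspondence line is `vertex_id  mixed_cell_id  t`, with vertex
ids stable across interior frames so trajectories can be traced.
`retired_vertices` counts correspondence hand-offs at topology changes
and at the two endpoint frames (which are built from their own
complexes). `--report-only` prints the superimposition census — the
count of intermediate cells per dimension tuple — without meshing.

The same pipeline is available as a library:

```python
from skinmorph import read_pdb, generate_morph, MorphConfig
states = generate_morph(read_pdb("two.pdb"), read_pdb("three.pdb"),
                        MorphConfig(frame_count=100, mesh_resolution=0.3))
```

## Hyperboloid sheet convention

The standard form x₁² + x₂² − x₃² = ±R² (R² = |w_X|/2) needs a sheet
selection rule. `skinmorph` orients the symmetry axis along the Delaunay
edge for edge-type cells and along the dual Voronoi edge for
triangle-type cells, and takes the sign of the right-hand side from w_X
(positive: one sheet) for edge cells and from −w_X for triangle cells.
This is exactly the convention under which the per-cell quadric values
agree on shared mixed-cell facets, which the test suite asserts.
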