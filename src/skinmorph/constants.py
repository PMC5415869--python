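"""Centralised numerical tolerances (all on Angstrom / Angstrom^2 scales)."""

#: absolute tolerance for scalar comparisons on weight-scale quantities
TOL_ABS = 1e-9

#: tolerance for affine-rank / dimension decisions on realised cells
RANK_TOL = 1e-7

#: magnitude of the deterministic symbolic-style jitter applied to
#: near-degenerate inputs of the generic complex builder
JITTER_SCALE = 1e-8

#: |implicit value| bound enforced on mesh vertices after projection
MESH_PROJECT_TOL = 1e-6

#: |w_X| below this floor makes the weight-ratio propagation rule singular
#: (cone apex); the caller re-projects instead of scaling
WEIGHT_FLOOR = 1e-8
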