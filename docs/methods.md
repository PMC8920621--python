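# Methods

## Scope and model

dermamesh reconstructs isosurfaces from regular scalar volumes by
marching cubes and implements the PASI-based clinical calculus for
two-arm psoriasis trials. A volume is a 3D grid of finite scalar
samples with strictly positive per-axis spacing; index `(x, y, z)` maps
to the physical point `origin + (x·ΔX, y·ΔY, z·ΔZ)`. All interpolation
happens in index space; physical spacing is applied when vertices are
emitted, so anisotropic stacks (in-plane pixel pitch much finer than the
slice interval) are handled without resampling.

## Case tables

Corner numbering is fixed by the trilinear corner weights: D0=(0,1,0),
D1=(0,0,0), D2=(1,0,0), D3=(1,1,0) on the z=0 face and D4..D7 the same
cycle at z=1. The 256-case triangle table is generated at import time:
for a given corner sign pattern the crossed edges are paired on each of
the six faces (a face with two crossed edges joins them; a face whose
inside corners sit on a diagonal — the classic ambiguous configuration —
cuts each inside corner off with its two adjacent crossed edges), the
pairs are chained into closed polygons, and each polygon is fan
triangulated. Because the ambiguous-face rule depends only on the
face's own sign pattern, the two cells sharing a face always agree, so
extracted meshes are crack-free; closed analytic fixtures come out
watertight with the expected Euler characteristic (2 for a sphere, 0 for
a torus). On every non-ambiguous pattern the triangle set coincides with
the standard published table (verified in the tests against an
independent implementation); on ambiguous patterns the diagonal
resolution may differ from the classic table — both resolutions are
valid topologies of the same sign pattern, and triangle counts agree in
all 256 cases.

Ties are broken toward inside: the inside rule is `f ≥ Q` by default
(`>` available), so a sample exactly at the isovalue is inside,
deterministically.

## Edge interpolation

`linear` places the vertex at `t = (Q − v_a)/(v_b − v_a)` along the
crossed edge, clamped to [0, 1]; when both endpoints equal `Q` the
midpoint is used. `midpoint` (alias `median`) places it at `t = 1/2`
regardless of the samples — for an x-edge at grid `(x, y, z)` the vertex
is `(x + 1/2, y, z)`, and analogously for y- and z-edges. The two modes
therefore share topology exactly, and every midpoint vertex lies within
half an edge of its linear counterpart. Each interpolation strategy
carries a division counter; the midpoint strategy performs zero
divisions per vertex, which is the machine-independent statement of its
arithmetic advantage (wall-clock comparisons are printed by the
benchmark command but asserted nowhere — they depend on the host).

Each crossed global edge is computed once (canonical orientation from the
lower grid vertex) and shared by all adjacent cells, so shared-edge
vertices are bit-identical and deduplication is exact. Triangles whose
vertices coincide exactly (possible in linear mode when a sample ties the
isovalue) are dropped at emission and counted.

## Normals and winding

Per-grid-vertex gradients use central differences
`qX = (f(x+1) − f(x−1))/(2ΔX)` in the interior; at the boundary the
centered stencil does not exist and a one-sided difference is used
instead (a deliberate, documented fallback). Vertex normals interpolate
the two endpoint gradients at the vertex's `t` (hence at the edge
midpoint in midpoint mode), are negated so they point toward decreasing
field values — outward for positive-inside signed-distance fields — and
normalized; a vanishing gradient falls back to the triangle's geometric
normal. Table winding is chosen so geometric triangle normals agree
with this orientation (counter-clockwise seen from the normal side).

## Volume ingestion

DICOM series are ordered by image position along the stack normal, then
instance number, then file order; per-slice rescale slope/intercept are
applied; slice spacing comes from positions (mean absolute gap), a
manifest override, or slice thickness. Only samples, spacing and origin
survive into the volume object — patient-identifying metadata is
structurally unreachable, which the tests assert. Raster export uses
full-range min–max windowing by default (skin-CT intensities have no
Hounsfield convention; an explicit center/width window is available),
mapping onto 8-bit monotonically, constant slices to 0. Raster stacks
reload in lexicographic (or explicit) order. A raw little-endian float32
grid with a JSON sidecar (dims, dtype, spacing, origin) serves as the
interchange format for the CLI.

## Synthetic fixtures

The generator produces signed-distance spheres and tori (positive
inside), affine ramps, and seeded band-limited Gaussian noise
(white noise smoothed with a σ=2 voxel Gaussian). These emulate the
geometry of closed lesion surfaces and irregular texture at controlled
resolution; they do not emulate confocal speckle, attenuation with
depth, or scanner artifacts, so passing tests certify the reconstruction
machinery, not robustness to real acquisition noise. Default test grids
are 32³–40³ at spacing 0.2 (sphere radius 2.05, torus ring 1.8/tube
0.85), chosen so several hundred cells cross the surface while the whole
suite stays fast; the acceptance script uses a 48³ sphere and 32³ noise
field for the same reason. Fixture radii are deliberately incommensurate
with the grid so no sample ties the isovalue.

## Clinical calculus

PASI, ΔPASI and ΔPASI% are exact arithmetic on validated scores
(E, I, D integer 0–4; P integer 0–6; PASI ∈ [0, 72]). Area percentages
map to P by the standard bins 0 → 0, (0,10) → 1, [10,30) → 2, [30,50) → 3,
[50,70) → 4, [70,90) → 5, [90,100] → 6 (configurable). Efficacy
categories use the conventional 90/60/30 % regression cut-offs, closed
below (a reduction of exactly 60 % is markedly effective); both the
cut-offs and the boundary convention are explicit parameters. Printed
comparisons round half-up to two decimals, matching clinical reporting
style (bankers' rounding would differ on exact halves).

The t test is Welch's by default (robust to unequal variances, with
Welch–Satterthwaite degrees of freedom); the pooled-variance Student
variant is available via `equal_var=True`. The χ² test is Pearson's
without continuity correction on 2×k tables (df = k − 1), refusing
tables with a zero marginal. Published arm-level summaries reproduce
exactly from their inputs for the observation arm; the control arm's
printed ΔPASI (18.84) is not derivable from its printed means
(28.60 − 9.41 = 19.19, plausibly a mean-of-differences vs
difference-of-means discrepancy in the source report), so the package
computes but does not assert that arm, and reported p-values are left to
the caller's interpretation.

## Numerical choices and limitations

- Dedup tolerance defaults to 1e-9 × bounding-box diagonal; shared-edge
  vertices are bit-identical, so the tolerance only guards float noise.
  Deduplication is grid-hash based, first-seen representative, normals
  averaged then renormalized, winding preserved, idempotent.
- Mesh I/O (binary STL, ascii OBJ/PLY) goes through trimesh; STL stores
  a raw soup, so connectivity is rebuilt by dedup on read. Empty meshes
  write valid empty files and read back error-free.
- Comparisons against the independent marching-cubes oracle are done on
  grids with small physical extent because the oracle stores vertices in
  float32; at large coordinates its own storage rounding exceeds the
  comparison tolerance.
- Known limitations: no asymptotic-decider disambiguation (the fixed
  face rule is consistent but may differ from the trilinear topology in
  ambiguous cells), no multi-frame DICOM, no mesh simplification or
  repair, no GPU path, and no modelling of confocal optics.
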