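# dermamesh

Surface reconstruction of stacked skin-CT (in-vivo confocal microscopy)
slices by marching cubes — with either classic linear edge interpolation
or a faster, division-free **midpoint ("median") edge rule** — together
with the PASI-based clinical calculus used to evaluate psoriasis
treatment in two-arm trials.

It is written for researchers who (a) reconstruct 3D lesion surfaces from
grayscale slice stacks (DICOM series, BMP/PNG/JPEG stacks, or raw grids)
and (b) score those lesions clinically and compare treatment arms.

## The methods

**Marching cubes.** A scalar volume `f(X, Y, Z)` with per-axis spacing
(ΔX, ΔY, ΔZ) is marched cell by cell. Each cell's 8 corner samples
D0..D7 are classified against an isovalue `Q` (corner inside when
`f ≥ Q`), the resulting 8-bit pattern selects a triangle configuration
from a 256-case table, and each triangle vertex is placed on a crossed
grid edge. Two placement rules are provided:

- *linear*: `t = (Q − v_a) / (v_b − v_a)` along the edge — the classic
  secant crossing, one division per vertex;
- *midpoint*: the geometric midpoint of the crossed axis-aligned edge,
  `(x + 1/2, y, z)` for an x-edge (and analogously for y/z) — independent
  of the sample values, no division at all. At the 2–5 mm slice
  intervals typical of clinical stacks the two placements are nearly
  indistinguishable, so the cheaper rule wins on speed.

Both rules use the same crossed edges, so triangle count, vertex count
and connectivity are identical across modes; only vertex positions
differ, by at most half an edge. In-cell values follow the trilinear
blend of the corner samples; vertex normals come from central-difference
gradients `qX = (f(x+1) − f(x−1)) / 2ΔX` (one-sided at the volume
boundary), interpolated along the crossed edge and oriented toward
decreasing field values.

**PASI.** For the four body regions (head, upper limbs, trunk, lower
limbs; weights 0.1/0.2/0.3/0.4) with erythema/infiltration/desquamation
scores E, I, D ∈ 0..4 and area score P ∈ 0..6:

```
PASI = Σ_r (E_r + I_r + D_r) · P_r · w_r          ∈ [0, 72]
ΔPASI = PASI_before − PASI_after
ΔPASI% = 100 · ΔPASI / PASI_before
```

ΔPASI% maps onto the efficacy categories cured / markedly effective /
effective / ineffective at the 90/60/30 % regression cut-offs; an arm's
*total effective rate* is the share of its patients in the top three
categories. Arms are compared with a Welch t test (summary statistics)
and a Pearson χ² test (category counts), and itching on the 0/2/4/6
scale.

## Worked example

```bash
python examples/reconstruct_sphere.py
```

```
  linear: 3980 triangles, 1992 vertices, watertight=True, Euler=2, radial error mean=0.0006 max=0.0021 (bound sqrt(3)h=0.3464), divisions=1992
midpoint: 3980 triangles, 1992 vertices, watertight=True, Euler=2, radial error mean=0.0355 max=0.0901 (bound sqrt(3)h=0.3464), divisions=0
```

Both modes produce the same closed genus-0 mesh (Euler characteristic 2,
no boundary edges); the linear mode is an order of magnitude closer to
the true sphere while the midpoint mode needs zero divisions — the
arithmetic the midpoint rule removes. `examples/clinical_summary.py`
prints the trial-level calculus:

```
observation dPASI  = 22.64 points
observation dPASI% = 80.14%
total effective rate: observation 88.76% vs control 71.07%
effective vs ineffective chi2 = 34.73 (df=1), p = 3.79e-09
post-treatment itching Welch t = -8.76 (df=708), p = 1.40e-17
```

i.e. the combined-treatment arm lost 22.64 PASI points (an 80.14 %
reduction), its effective rate exceeds the control arm's, and both group
differences are significant at the 0.05 level.
`examples/benchmark_modes.py` compares the two extraction modes on a
torus, printing counts, displacement statistics and (machine-dependent,
informational) wall-clock times.

## Command line

```bash
dermamesh simulate  --field sphere --dims 48 --out vol.raw
dermamesh extract   --input vol.raw.json --isovalue 0 --mode midpoint --out mesh.stl
dermamesh report    --mesh mesh.stl
dermamesh benchmark --input vol.raw.json --isovalue 0
dermamesh pasi      --assessments assessments.csv
dermamesh efficacy  --outcomes outcomes.csv
```

Assessment CSVs carry `patient_id, region, E, I, D, P, timepoint`;
outcome CSVs carry `arm, cured, markedly_effective, effective,
ineffective`.

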