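# cranioshape

Quantification of cranial asymmetry — deformational plagiocephaly (DP) in
particular — from infant head 3D point clouds.

DP is a positional flattening of one posterior quadrant of an infant's
skull, often with compensatory frontal bossing on the same side (the
"parallelogram" head). It is conventionally screened with calliper and tape
measurements condensed into a handful of indexes. `cranioshape` implements
those classical indexes from a 3D model and, alongside them, a global
shape descriptor that uses the whole point cloud: the head is compared to
its own ideal (symmetric) ellipsoid and the deviation field is expanded in
spherical harmonics, whose degree-2/order −2 coefficient isolates exactly
the diagonal surplus/deficit pattern that DP produces.

The package is aimed at researchers working with low-cost cranial surface
scans (photogrammetric caps, structured light, or any source of a
few-hundred-point surface cloud in mm) who need automatic, reproducible
deformation indexes and a screening call per head.

## Method

For a head cloud `O` registered to its anatomical frame (origin at the
inter-preauricular midpoint, +X anterior through the glabella, +Y the
patient's left):

1. **Ideal ellipsoid.** The axis-aligned triaxial ellipsoid `E` (centre
   `x₀,y₀,z₀`, semi-axes `aₓ,a_y,a_z`) is fitted to the cloud by linear
   least squares on `Ax² + By² + Cz² + Dx + Ey + Fz = 1`. Being symmetric
   about the anteroposterior axis, `E` is blind to the asymmetry being
   measured.
2. **Orthogonal distances.** Every point `P ∈ O` is projected to its foot
   point `Q_P` on `E` (safeguarded Newton on the Lagrange parameter of the
   closest-point conditions), giving a signed distance `d` (+ outside) and
   chart coordinates `(θ, φ)` — the geocentric latitude/longitude of `Q_P`
   about the ellipsoid centre:

       P = E(θ, φ) + v̂(θ, φ) · SH(θ, φ, l_max) + ε

   with `v̂` the outward surface normal at `Q_P`.
3. **Spherical-harmonic expansion.** `SH(θ, φ, l_max) = Σ f_l^m Y_l^m(θ, φ)`
   is fitted to the scattered distances by ordinary least squares, using
   4π-normalized real harmonics without the Condon–Shortley phase
   (`Y₀⁰ ≡ 1`). The coefficient **f₂⁻²**, which varies as `sin 2φ` and
   splits the head into four alternating quadrants, is the DP index:
   `|f₂⁻²| > 0.42` at `l_max = 4` flags a head as DP, and its sign encodes
   the flattened side (positive left, negative right).

The classical measurements are computed from the same cloud: the cranial
perimeter CP (maximum convex-hull perimeter over planes containing the
ear-to-ear axis), the oblique diagonals `a`, `b` at ±30° from the
anteroposterior axis within that maximal slice, head length `c` and width
`d`, and from them

    CI = 100·d/c    AI (CVAI) = a − b    OCLR = 100·a/b
    AAI = a_frontal − b_frontal    PAI = a_back − b_back

where each diagonal is split at the anatomical origin into its frontal and
back half — a split impossible with callipers and robust against frontal
compensation. A head is DP by the index rule when any of |AI|, |AAI|, |PAI|
strictly exceeds 4 mm or OCLR leaves 94–106 %; CI outside 75–95 % raises an
informational brachy-/scaphocephaly flag only.

## Worked example

A synthetic head with an 8 mm back-left flattening plus ipsilateral frontal
compensation, analysed end to end:

```python
from cranioshape import Bump, SyntheticSpec, analyze_head, generate_head

spec = SyntheticSpec(
    deformations=(Bump(azimuth_deg=135.0, lat_deg=10.0, amplitude_mm=-8.0),),
    compensation=True,
    seed=42,
)
head, truth = generate_head(spec, id="demo-dp")
report = analyze_head(head, lmax=4, lmax_sweep=[2, 3, 4, 5])
```

which prints (via the snippet in `docs/methods.md`):

```
head demo-dp: 530 points
fitted ellipsoid semi-axes (mm): [85.02 65.4  60.31]
CP = 474.1 mm, CI = 77.6 %
AI = 10.0 mm, AAI = 4.5 mm, PAI = 5.6 mm, OCLR = 106.6 %
f2^-2 (lmax=4) = 1.292   (threshold 0.42)
expansion RMSE = 0.30 mm
classification: indexes -> DP, spherical harmonics -> DP
  lmax=2: f2^-2 = +1.426, RMSE = 0.55 mm
  lmax=3: f2^-2 = +1.405, RMSE = 0.39 mm
  lmax=4: f2^-2 = +1.292, RMSE = 0.30 mm
  lmax=5: f2^-2 = +1.296, RMSE = 0.28 mm
```

The head is flagged DP by both routes: the flattening opens a 10 mm gap
between the oblique diagonals, and f₂⁻² = +1.29 is far above the 0.42
threshold with the positive sign reporting a left-sided flattening. The
sub-millimetre RMSE shows a degree-4 expansion already reconstructs the
distance field to within the measurement noise.

The same pipeline is scriptable from the shell:

```
cranioshape simulate --out cohort/ --n-healthy 8 --n-dp 10 --seed 7
cranioshape analyze cohort/P1.ply --landmarks cohort/P1.landmarks.json --out P1.json
cranioshape batch cohort/ --out cohort.csv
cranioshape compare --cohort cohort.csv --out stats.csv
```

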