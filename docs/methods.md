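# Methods

## Model

A head surface is represented as an unordered point cloud in millimetres
(typically ~530 points from a cap-based surface scan) together with three
manually identified landmarks: the left and right preauricular points and
the glabella (the point between the eyes). All analysis happens in the
anatomical frame these landmarks define: origin at the inter-preauricular
midpoint, +X anterior through the glabella, +Y the component of the
right-to-left inter-preauricular vector orthogonal to X (the patient's
left), +Z = X × Y toward the vertex. The transform is rigid; models stay in
true mm (no scale normalisation).

The core assumption is that an undeformed cranium is well approximated by
a triaxial ellipsoid whose axes are parallel to the anatomical frame.
Because the fitted ellipsoid is constrained to be axis-aligned, it is
symmetric about the anteroposterior axis and cannot absorb the very
left/right asymmetry being measured; a unilateral posterior flattening
therefore appears as a signed residual field — negative (inside the
ellipsoid) over the flattened quadrant, positive over the contralateral
quadrant that the compromise fit pushes inside the data.

That residual field d(θ, φ), indexed by the geocentric latitude/longitude
of each point's foot point on the ellipsoid, is expanded in real spherical
harmonics up to degree l_max by ordinary least squares on the scattered
samples. Under the 4π-normalized real convention without Condon–Shortley
phase, Y₂⁻² varies as sin 2φ around the equator: four alternating
quadrants, two posterior and two anterior. A diagonal deficit/surplus
pattern — the DP signature — loads almost entirely on f₂⁻², which is the
screening statistic. The convention is immutable and recorded in every
report because the decision threshold (0.42) is only meaningful under a
fixed normalization.

## Pipeline stages and numerical choices

**Ellipsoid fit.** Linear (algebraic) least squares on
Ax² + By² + Cz² + Dx + Ey + Fz = 1, converted to centre and semi-axes by
completing the square. Algebraic rather than geometric-distance least
squares: it is closed-form, deterministic, and for near-ellipsoidal clouds
the two differ negligibly. The centre is free (6 parameters); rank
deficiency (coplanar clouds) and non-positive quadratic coefficients raise
fit errors naming the offending axis. At least 9 points are required.

**Foot points.** The closest surface point solves
q_i = c_i + a_i²(p_i−c_i)/(a_i²+t) with t the root of
F(t) = Σ a_i²(p_i−c_i)²/(a_i²+t)² − 1, which is strictly decreasing on
(−a_min², ∞). A bracketed Newton iteration with bisection fallback is
globally convergent; tolerance 1e-10 (relative) on the t-step, at most 100
iterations, vectorized over all points of a head. Signed distance is
+‖p−Q_P‖ outside, −‖p−Q_P‖ inside. Points on the medial axis (including
the exact centre), whose foot point is not unique, are resolved
deterministically along the shortest semi-axis and flagged ambiguous; they
cannot occur for surface data.

**Chart.** Latitude is geocentric (angle from the ellipsoid-centre
equatorial plane), not geodetic; the chart only indexes the reference
surface, and the geocentric form is cheap and invertible. Longitude is
wrapped to [0, 360).

**Expansion.** Ordinary least squares on the (n, (l_max+1)²) design of
basis values; no weighting and no regularization by default. An optional
ridge penalty (default 0, recorded in the report when used) exists for
clouds whose cap coverage is partial enough to ill-condition high degrees;
with the default −25° cap and l_max ≤ 10 the design is comfortably
conditioned. A condition number above 1e8 (unregularized) raises an error
rather than returning silently unstable coefficients. Default l_max = 4:
low degrees carry the DP pattern, and the degree-4 truncation reconstructs
smooth heads to sub-millimetre RMSE while leaving the coefficient of
interest uncontaminated by noise fitting; an optional sweep (default
2..10) refits independently per degree.

**Anthropometry.** The cranial perimeter plane is searched over planes
containing the Y direction, tilted about Y on a 1° grid within ±30° of
horizontal, with offsets on a 2 mm grid spanning the cloud; points within
a ±4 mm slab are projected into the plane and the perimeter of their 2D
convex hull scored (a tape wraps convexly). The finite slab and grids are
needed because a ~530-point cloud populates any exact plane with measure
zero; the constants are exposed in the effective config of every report.
Near-ties within 0.1% of the maximal perimeter (e.g. a near-spherical
head, where every tilt is equivalent) are broken deterministically toward
the least-tilted, most central plane. The oblique chords are measured
along the ±30° rays through the anatomical origin within the maximal
slice, so a = a_frontal + a_back holds identically and AI = AAI + PAI is
an exact decomposition. Head length c is the X extent of the maximal
slice polygon; width d the Y extent of the full cloud.

**Cephalic index.** CI = 100·d/c (width over length), the standard
cephalic index: clinical normal ranges of 75–95% only make sense with the
shorter dimension in the numerator.

**Screening.** The asymmetry rule is strict: |AI|, |AAI|, |PAI| abnormal
only when strictly greater than 4 mm, OCLR normal on the inclusive band
[94, 106]%. Published per-head validation tables flag magnitudes of 5 and
above while leaving 4 unflagged, which fixes the strict reading; the OCLR
bounds are taken inclusive for symmetry. The spherical-harmonic rule is
likewise strict: DP iff |f₂⁻²| > 0.42 on the raw coefficient scale (the
10× scale some plots use for visual comparison with mm-valued indexes is
display-only). CI out of range flags brachy-/scaphocephaly informationally
and never enters the DP call. Group comparisons take absolute values per
parameter, report Shapiro–Wilk (per group) and Levene checks without
gating, and use the pooled-variance two-sided Student t-test, ranked by
ascending p with no multiple-testing correction (ranking, not inference,
is the point). Ratio-valued OCLR enters as OCLR − 100 so that a symmetric
head scores zero.

**Reports.** Every report embeds the fitted ellipsoid, measures, indexes,
the full (l, m, coefficient) table with its normalization tag, per-degree
sweep results, screening flags and the complete effective configuration.
JSON serialization sorts keys and rounds floats to 9 significant digits,
so identical inputs give byte-identical reports.

## Synthetic data

The generator exists so that every stage can be tested against known
ground truth. A head is a triaxial ellipsoid (default semi-axes 85, 65,
60 mm — infant-head-sized) sampled at n = 530 near-equal-area sites
(Fibonacci spiral) restricted to latitude ≥ −25°, emulating a measurement
cap that leaves the head base uncovered. Deformations are smooth Gaussian
bumps in great-circle angle (SD ≥ 20°, default 45°) applied along the
outward surface normal; measurement noise is Gaussian along the normal
(default SD 0.3 mm). Landmarks sit exactly on the undeformed ellipsoid, so
generated heads are born aligned; alignment robustness is tested by
applying known rigid transforms. Bumps are deliberately parameterised by
angular width rather than by planting a spherical harmonic, so coefficient
recovery is a non-circular check.

Cohorts mirror a small clinical study: regular heads are noise-only; DP
heads carry one inward bump of 5–10 mm (drawn uniformly) centred in the
posterolateral occipital band — azimuth uniform over [120°, 160°] or its
mirror [200°, 240°], latitude uniform in [0°, 15°] — because DP is a
unilateral flattening clearly off the midline near ear level; a
midline-centred flattening is a symmetric, brachycephaly-like shape with
no diagonal asymmetry for any index to detect. Half the DP heads receive
frontal compensation, modelled as the parallelogram deformity: an
opposite-sign bump at the azimuth mirrored across the ear-to-ear axis
(ipsilateral frontal bossing). An antipodal compensation was considered
and rejected: Y₂⁻² has even parity, so an antipodal opposite-sign pair
cancels f₂⁻² (and the oblique-diagonal difference) exactly, leaving a
shape that no asymmetry index — classical or spectral — can see, which is
not the clinical phenotype. Per-head semi-axes are jittered ±10% and
per-head seeds derive deterministically from the master seed.

What the generator does **not** emulate: real scalp softness and hair
artefacts, landmark placement error (available as an option, default off),
spatially correlated scanner noise, non-ellipsoidal normal head-shape
variation, and craniosynostosis shape families. Passing simulation tests
therefore demonstrates correctness of the computation and sensible
behaviour under the modelled conditions, not clinical performance.

## Test problem sizes

The suite favours sizes that keep the full run fast while leaving the
statistics meaningful: 100 seeded healthy heads for the false-positive
control of the 0.42 threshold (99th percentile of |f₂⁻²| ≈ 0.04, an order
of magnitude below the threshold); an 18-head cohort (8 regular + 10 DP)
for the sub-millimetre RMSE check; 50 seeded 18-head cohorts for the
parameter-ranking comparison; 200 replicates for planted-coefficient
bias/spread; a 2-million-vertex nearest-neighbour oracle for foot-point
distances (sharp to ~0.002 mm for points ≳2 mm off the surface, hence the
shell used in that test).

## Known limitations

- The ellipsoid fit is algebraic; for clouds that deviate grossly from an
  ellipsoid the algebraic and geometric fits diverge, and the resulting
  chart (not just the residuals) absorbs some deformation.
- The perimeter-plane search is a grid search; CP is resolved only to the
  grid (1°, 2 mm) and slab (±4 mm) constants.
- The 0.42 threshold is taken as given; no ROC refinement is attempted.
- Screening is binary (regular vs DP); severity staging and other
  deformities (brachycephaly beyond the CI flag, craniosynostosis) are out
  of scope.
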