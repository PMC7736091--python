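# Methods

## The measurement model

`hipmorph` operates on *annotations*, not pixels: per hip, two manually
traced open polylines (the acetabular arc from the outer upper margin to
the fossa floor, and the femoral arc from head onto neck), a manually
marked sourcil medial point, and the teardrop inferior point. Manual steps
of the clinical workflow are represented as input data and never computed;
automatic contour segmentation is explicitly out of scope.

All measurements are defined in a pelvic frame. Line *a* joins the two
teardrop inferior points; its unit direction is the pelvic horizontal and
the perpendicular obtained by rotating it so that it points toward
decreasing image *y* (on an upright film) is "superior". Sides are
inferred from image x-order — on an AP view the patient's right hip
appears on the image left — with an `infer_sides=False` override for
unusual orientations. Lateral, per side, points along line *a* away from
the pelvic midline. Because every direction is frame-relative, all three
angles are invariant under in-plane rotation, translation and uniform
scaling of the radiograph; this is enforced by property tests over random
similarity transforms.

Landmarks are extracted as follows.

* **Femoral head.** Three non-collinear points on the head are taken from
  the femoral arc: the vertex extremal in the superior direction, the
  vertex extremal in the lateral direction, and the intersection of the
  chord from that lateral vertex to the teardrop inferior point with the
  arc (of several crossings, the one closest to the teardrop). The head
  circle is the circumcircle of the three; a plausibility check warns when
  the median residual of head-region vertices (within 1.5 fitted radii)
  exceeds 5 % of the radius. A least-squares circle fit is deliberately
  *not* used as the estimator — the three-point circumcircle is the
  defined method; the residual check is only a sanity guard.
* **Acetabular lateral margin.** The more lateral of the acetabular arc's
  two endpoints; when the endpoints are tied within 1 px, the superolateral
  extremal vertex of the whole arc is used instead. One landmark serves
  both as the Sharp/CE rim point and as the sourcil lateral edge — the
  clinical definitions do not distinguish them, and a single anchor keeps
  the three angles mutually consistent.

Angles: Tönnis is `atan2` of the sourcil chord's superior component over
its lateral component (signed; positive = upsloping); Sharp is the acute
angle between the teardrop→margin line and line *a* (unsigned); CE is
`atan2` of the center→margin lateral component over its superior component
(signed; negative = deficient coverage). The CE "vertical" is the
perpendicular to line *a* by default; `vertical="image"` restores the
literal image-column reading (both agree on an un-tilted film).

Classification uses the standard cutoffs with strict inequalities exactly
as worded clinically: Tönnis > 10° and Sharp > 45° are dysplastic; CE
< 20° is dysplastic and 20° ≤ CE ≤ 25° borderline (the borderline class
exists only for CE). Dichotomizing CE collapses borderline+dysplasia to
"abnormal", equivalent to a single CE ≤ 25° cut.

## The SVM

The machine-learning assessor is a scikit-learn `SVC` with a polynomial
kernel of degree 2, penalty C = 0.3, and all remaining parameters at their
defaults (coef0 = 0, `gamma="scale"`), over the three angles per hip. One
consequence of coef0 = 0 is that the kernel is a *homogeneous* quadratic:
if the features were mean-centered first, the decision function would be
symmetric under negation of the standardized feature vector and one-sided
angle thresholds could not be represented (empirically, cross-validated
accuracy on clean threshold labels collapses from ≈0.97 to ≈0.64). The
pipeline therefore feeds raw angles by default; `SvmSpec(standardize=True)`
exists for experimentation. No train/test protocol is defined clinically,
so the package's default evaluation is stratified 5-fold cross-validation
with a fixed seed; the model fitted on all data is also exposed.

## Agreement statistics

Confusion-table statistics (accuracy, sensitivity, specificity,
false-positive rate, per-class recall, Cohen κ) are computed in exact
rational arithmetic (`fractions.Fraction`) and rounded only for reporting
(percentages to one decimal, κ to three). The McNemar test is the exact
two-sided binomial on the discordant pair counts at *any* sample size —
this convention reproduces the validation study's printed p-values from
its printed tables, which the continuity-corrected chi-square (available
via `exact=False`) does not exactly. Tables larger than 2×2 use Bowker's
symmetry generalization; discordant pairs summing to zero contribute
nothing and drop one degree of freedom.

ROC analysis places candidate thresholds at midpoints between consecutive
distinct scores (plus ±∞), so a chosen operating point always falls
between observations; AUC is the trapezoid rule over the (FPR, TPR)
staircase with tied FPR points ordered by TPR, which equals the
Mann–Whitney concordant-pair fraction with half-credit for ties (verified
against exhaustive pair counting and scikit-learn). The operating
threshold maximizes Youden J, ties resolved toward higher specificity; the
`lower_is_positive` orientation serves the CE angle, where smaller values
indicate disease. Cronbach α for test–retest reliability uses the two-item
form α = 2·(1 − (Var m₁ + Var m₂)/Var(m₁+m₂)) with sample variances.

## Synthetic data

**Hip phantoms.** The generator inverts the angle definitions analytically
in teardrop-anchored (lateral, superior) coordinates: the rim point *P*
lies on the ray from the teardrop at the Sharp angle above line *a* at a
fixed teardrop–rim distance (50 px); the head center is *C* = *P* − ρ·(sin
CE, cos CE) with ρ = √500 px, which makes *P* exactly the intersection of
the Sharp ray with the ray from *C* at the CE angle off the vertical; the
sourcil medial point sits 20 px medially of *P* along a chord at the
Tönnis angle. These scales reproduce the package's canonical worked
geometry (teardrop (80, 120), head center (100, 100), rim (110, 80)) and,
angles being scale-invariant, do not affect measured values. The femoral
arc samples the head circle (radius 25 px by default) over a 300° sweep
from 30° medial of the superior pole — wide enough that the teardrop chord
re-crosses the sampled arc everywhere inside the study's observed angle
ranges (Tönnis −8…33°, Sharp 30.6…55.6°, CE −4…47°); the acetabular arc is
a quadratic Bézier from the rim through the sourcil medial point to the
fossa floor. When Sharp + CE = 90° the two defining rays are parallel
(head center collinear with teardrop and rim) and construction is refused.
Optional Gaussian jitter (seeded) perturbs every contour vertex.

Numerical fidelity: noise-free phantoms measure back to their targets
within 0.011° worst-case over the study ranges at the default 100-point
arc sampling. The residual is polyline discretization — the medial head
point is an intersection with a chord of the sampled circle, whose sagitta
at 100 points is ~3×10⁻³ px; head-center recovery reaches 10⁻⁶ px only in
the dense-sampling limit (verified at 8000 points). Jitter sensitivity at
the canonical scale is ≈2.2° mean absolute angle error per 1 px of contour
jitter, dominated by the endpoint-anchored Tönnis and CE angles whose
lever arms (20 and ≈22 px) are short at this scale; the regression test
bounds it at 3°. On real films with head radii of hundreds of pixels the
same 1 px jitter corresponds to proportionally smaller angular error.

**Paired cohorts.** Per hip, a latent angle triple is drawn from a
trivariate normal with means (8.490, 39.897, 28.129)° and the reader SDs
(6.510, 4.178, 8.090)° of the validation cohort split into latent and
noise parts as σ_latent = σ·√0.9, σ_noise = σ·√0.1 — so two independent
observations of the same hip correlate at 0.9, the regime the validation
study reported. Physician and CAD observations add independent seeded
noise of that size; CAD additionally carries the study's mean offsets
(−0.523, +0.988, −1.292)°. Calibration prioritizes the paired correlation
over matching the CAD column SDs exactly. Inter-angle correlations default
to (Tönnis↔Sharp +0.4, Tönnis↔CE −0.6, Sharp↔CE −0.5): clinically
plausible (a steeper sourcil and a flatter socket both accompany reduced
lateral coverage), explicitly not study-reported, and configurable.

What the generators do **not** emulate: osteophytes and margin-definition
ambiguity, occluded or incomplete traces, severity-dependent reader bias,
non-Gaussian tracing error, and pixel appearance. Passing round-trip and
cohort tests therefore validates the geometry and the statistics code, not
segmentation robustness on real radiographs.

## Numerical choices and degenerate inputs

- Collinearity: three points are degenerate when triangle area
  < 10⁻⁹ × span², span the largest pairwise distance.
- Segment–polyline intersections within 10⁻⁶ px of the segment start are
  discarded (a chord anchored on the polyline must not report its anchor);
  duplicate hits at shared polyline vertices are merged at the same
  tolerance.
- Vectors with norm < 10⁻¹² are zero for angle purposes; arccos arguments
  are clamped to [−1, 1].
- Extremal-vertex ties (within 10⁻⁹ of the span) break toward the larger
  projection on the clockwise perpendicular of the query direction.
- Per-hip measurement failures are reported per side and do not abort the
  contralateral hip; both failing is an error.
- Angles are reported to three decimals; head geometry to six.

## Problem sizes

Default verification sizes — 500 phantoms for round-trip bounds, 248 hips
per simulated cohort (matching the validation cohort), 500 hips for SVM
cross-validation, 200 score sets for the AUC identity, 100 transforms for
invariance — were chosen so each property is exercised across its input
range while the full suite stays interactive (a few seconds end to end).

## Known limitations

- The system is semiautomatic by design: tracing quality bounds
  measurement quality, and the phantom jitter analysis above quantifies
  that sensitivity only at the phantom scale.
- The sourcil lateral edge is identified with the acetabular lateral
  margin; films where osteophytes separate the two are outside the model.
- Side inference assumes an approximately upright AP film; heavily rotated
  images require explicit side labels.
- The SVM's clinical training protocol (which angles, which split) is not
  standardized; the package's CV protocol is a documented default, not a
  claim about the original system.
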