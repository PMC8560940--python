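# Methods

## Measurement model

The voxelwise fat fraction is the ratio of the fat channel to the summed
channels, `FF = F / (W + F)`, computed only where `W + F` exceeds a
configurable signal floor (default 0). Voxels at or below the floor carry no
Dixon signal (air, background) and are marked *undefined*: they are excluded
from every FF average but still counted in volumes, and their count is
reported per muscle so users can audit masks that leak into background.
Defined FF values are clipped to [0, 1]; with non-negative channels the clip
can only act through the floor interaction and never moves interior values.

Per-muscle metrics are computed on the **muscle bulk**: the label restricted
to axial slices between the lesser-trochanter tip and the ASIS landmark,
inclusive at both ends (a degenerate single-slice bulk is legal). Metrics
are

* `mean_ff` — unweighted arithmetic mean of defined FF over bulk voxels;
* `volume_ml` — labelled bulk voxel count × voxel volume (0.47 × 0.47 ×
  1.95 mm³ by default, the emulated acquisition's voxel);
* `lean_volume_ml` — `volume × (1 − mean_ff)`;
* normalized (lean) volume — divided by Boer lean body mass
  (male `0.407·weight + 0.267·height − 19.2`,
  female `0.252·weight + 0.473·height − 48.3`; weight kg, height cm).

A subject's side-mean FF is the unweighted mean of the left and right
`mean_ff`, not a voxel-pooled mean — the two muscles get equal weight
regardless of size. Optional binary erosion of the label (radius in voxels,
default 0) is exposed for users worried about intermuscular-fat cross-talk
at label boundaries; labels drawn inside the muscle should not need it.

Geometry is never repaired: channels must share shape and affine within
1e-4 mm, labels and landmarks must sit on the study grid, and any mismatch
is an error rather than a resample. Axis roles (left-right,
anterior-posterior, superior-inferior) are read from the NIfTI orientation
codes; the slice axis for bulk extraction is the superior-inferior one.
Landmarks may be given in voxel indices or world mm (converted through the
affine and rounded; round trips are exact to within half a voxel).

Activity grouping partitions weekly exercise hours as [0, 4) → Low,
[4, 8] → Mid, (8, ∞) → High; both boundary values fall in Mid, which is the
one consistent reading of "less than 4", "between 4 and 8", "more than 8".
Oxford Hip Scores grade as 0–19 Severe, 20–29 Moderate, 30–39 Mild, 40–48
Satisfactory.

## Synthetic phantoms

`generate_phantom` renders two ellipsoidal muscles (left/right) on a
96 × 96 × 48 grid at the Dixon voxel size by default (≈1.8 × 10⁴ bulk voxels
per muscle — large enough for stable averages, small enough for seconds-scale
tests). The signal model is `W = PD·(1 − ff)`, `F = PD·ff` with proton
density PD = 100, so the noiseless pipeline recovers the true field exactly,
by construction. FF fields can be constant, a linear superior-inferior
gradient, or constant plus Gaussian texture. Channel noise is Gaussian by
default (Rician selectable); at the SNR used here the FF ratio is insensitive
to the choice. After adding noise the channels are clipped at zero, as
magnitude images cannot be negative; at PD/sd = 50 the clip is a ≪1-in-10⁶
event and its bias is negligible. An optional subcutaneous-fat annulus
(FF 0.9) surrounds the muscles to exercise masking; it is never labelled.
Ground truth (bulk-mean FF, voxel count, volume) is computed inside the
generator by direct summation of the noiseless field and stored with the
spec and seed, so truth is recomputable and independent of the measurement
path.

What the phantoms do **not** emulate: anatomical muscle shapes, Dixon
reconstruction physics (echoes, fat spectrum, B0), bias fields, motion, and
partial-volume mixing at muscle boundaries. Passing tests therefore
demonstrate correctness of the masking, averaging, volumetrics and
statistics — not robustness to segmentation error or acquisition artifacts.

## Synthetic cohorts

`generate_cohort_table` draws a four-group cohort (hip-pain patients plus
Low/Mid/High activity) whose demographics default to the studied
population's structure: group sizes 19/13/18/20, the observed male/female
splits, group-specific age ranges, BMI and height distributions (weight is
derived as BMI·height² so the anthropometrics stay consistent). Fat
fractions come from one of two generating models:

* **linear** (default): `FF% = β₀ + β_male·male + β_BMI·BMI + β_age·age +
  β_group + β_side·right + ε`, with defaults β_male = −3.8, β_BMI = 0.9,
  β_age = 0.1, group offsets 7.2/5.2/1.8 (Pain/Low/Mid vs High) and
  β_side = −3.0, ε ~ N(0, 4²) — effect magnitudes of the scale reported for
  this population, so recovery tests run in a realistic regime. β₀ = −5.2
  places the High-activity group mean near 15% FF.
* **direct**: per-group draws, lognormal by default (group medians below
  means in such cohorts indicate right skew) with means 27.7/19.1/18.0/14.7
  and SDs 7.7/5.5/6.3/4.7 percent, a per-subject additive left-right offset
  (default 3.3 points, left higher) plus small per-side noise.

Generated FF is truncated to [0.5, 70]%; the exact parameters used are
returned alongside the table so estimator recovery is testable.
`generate_imaging_cohort` then gives every tabular subject a phantom whose
constant per-side FF equals their tabular truth, binding the imaging and
statistical layers together. All generators are deterministic given their
seed.

Healthy subjects carry no OHS questionnaire; when the regression needs a
complete OHS column they are assigned grade 4 (Satisfactory), the grade a
symptom-free hip would score.

## Statistics

* Quantiles (median, IQR, the outlier fence) use linear interpolation of
  order statistics by default; Tukey hinges are selectable. The outlier rule
  flags values **strictly above** Q3 + 1.5·IQR.
* Kruskal–Wallis uses the tie-corrected H with the χ² approximation
  (df = k − 1); for total n ≤ 9 the p-value comes from full enumeration of
  group assignments instead. Degenerate all-equal input returns H = 0,
  p = 1, flagged.
* The post hoc after a Kruskal–Wallis omnibus is Tukey HSD applied to the
  pooled rank transform (raw-scale HSD selectable); zero-variance input
  yields p = 1 rather than NaN.
* Wilcoxon signed-rank drops zero differences (Pratt handling available via
  the approximate path), computes an exact two-sided p for n ≤ 25 by
  dynamic programming over sign patterns — average ranks are doubled to
  integers, so ties are exact too — and otherwise uses the normal
  approximation with continuity and tie correction. The median paired
  difference is reported as the effect.
* The hierarchical linear regression enters predictor blocks sequentially
  (gender, BMI, age, activity, OHS grade, side, pain side by default) on
  side-level rows. A block is retained iff its partial F test is significant
  at α and R² strictly increases; non-retained blocks are removed before the
  next step, so the final model contains exactly the retained predictors.
  Activity is categorical with High as the reference level; coefficients are
  in FF percentage units. Coefficient p-values are reported both at entry
  and in the final model, since the two differ in general. Rank-deficient
  designs raise instead of silently dropping columns.
* Logistic models (inactive = Pain + Low vs Mid + High; patients vs all
  healthy) are maximum-likelihood fits on subject-level (side-mean) rows
  with Wald 95% CIs on the odds-ratio scale; perfect separation is detected
  and reported as an error.
* `sample_size_two_group` implements the standard normal-approximation
  formula `n = 2((z₁₋α/t + z_power)·sd/δ)²` per group (optional noncentral-t
  refinement). At δ = 3, sd = 4, power 0.8, two-sided α = 0.05 this gives 28
  per group.
* `power_delta_r2` evaluates the partial-F power with Cohen's
  f² = ΔR²/(1 − R²_full) and noncentrality λ = f²·n; λ = 0 returns α
  exactly.

Sides are treated as independent observations in the linear model, which
understates within-subject correlation; a mixed model would be the stricter
choice and is deliberately out of scope so results remain comparable with
the conventional analysis. No multiplicity correction is applied across the
report's many tests beyond the HSD family adjustment.

## Problem sizes and numerical conventions

Calibration checks use 2000 replicates for the rank tests and 1000 for the
regression F (binomial SE ≈ 0.005–0.007 at α = 0.05); estimator-bias checks
use 500 replicates at n = 140 rows, σ = 4. The group-difference validation
uses two 8-subject cohorts at the default phantom grid. These sizes give
Monte-Carlo error well inside the tolerances asserted while keeping the full
validation in the minutes range on one core.

Float comparisons in invariants use absolute tolerances of 1e-8–1e-13
depending on the arithmetic depth; the masked mean is asserted *equal* to an
explicit voxel-loop oracle because both traverse voxels in the same (C)
order. Channel co-registration tolerance is 1e-4 mm on affines. Seeds are
threaded through `numpy.random.default_rng` everywhere; per-subject phantom
seeds derive from the cohort seed by a fixed affine map modulo 2³¹ − 1.

## Known limitations

* Ellipsoid phantoms cannot probe segmentation quality or partial-volume
  behaviour at real muscle boundaries.
* The exact Kruskal–Wallis enumeration is practical only for tiny samples
  (n ≤ 9 by default); beyond that the χ² approximation is used, which is
  slightly conservative at small-but-not-tiny n.
* The Boer formula is an adult population estimate; normalized volumes in
  extreme anthropometric ranges inherit its bias.
* Logistic Wald CIs are symmetric on the log-odds scale and degrade near
  separation; profile-likelihood intervals are not implemented.
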