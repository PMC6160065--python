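# Methods

## The measurement model

A 3CCD camera records R, G, B on separate sensors behind bandpass filters.
Over a wound-bed ROI the channel means act as a three-band reflectance
measurement. The contrast of interest is hemoglobin oxygenation: around the
red band (~610 nm) deoxyhemoglobin absorbs roughly an order of magnitude
more strongly than oxyhemoglobin, so better-oxygenated tissue reflects more
red light and R−B rises with StO₂. The ratio indices serve as brightness
normalizations: (R−B)/G cancels any uniform per-image gain exactly, and
(R−B)/(R²+B²) divides the red-blue contrast by the squared channel
magnitude, so it *amplifies* as overall intensity drops — it is the index
most sensitive to the overall darkening of failing wounds.

All computation uses stored (gamma-encoded) 8-bit values rescaled to
[0, 1]; no linearization is attempted, matching how such cameras are used
clinically. Pixel coordinates are row-major with origin top-left; polygon
ROIs include pixels whose centers fall inside (even-odd rule); multiple
ROIs on one image are pooled area-weighted (each pixel counted once) into
one channel mean per image, because downstream modeling needs exactly one
feature row per debridement.

## Quality screening

Images are gated before analysis on three ROI measurements, each with a
configurable threshold:

| check | statistic | default gate |
|---|---|---|
| glare | fraction of pixels with any channel ≥ 250/255 | ≤ 0.05 |
| blur  | variance of a 3×3 Laplacian of luminance ((R+G+B)/3) | ≥ 1e-4 |
| blood | fraction of pixels with R − max(G,B) > 0.25 | ≤ 0.50 |

The blur gate is a focus measure: defocus suppresses high-frequency texture
and collapses the Laplacian variance by orders of magnitude. The defaults
were chosen so that clean renders from the synthetic generator pass and
injected artifacts fail; on real photographs they would need recalibration
against expert judgment.

## Normalization

Two stages, in this order:

1. **Hospital (cohort) normalization.** Each image's channel means are
   divided by its hospital's average R, G, B over the fit population. This
   cancels per-hospital camera gain exactly (verified to 1e-10 relative in
   the tests) and is what makes values comparable between operating rooms.
   The seven raw indices are computed from these normalized channels.
2. **Variable normalization.** Each index is divided by its pooled mean
   over the fit population, giving the seven "normalized" variables with
   population mean 1.

A structural subtlety: after stage 1 every hospital's mean normalized
channel is exactly 1, so the *difference* indices R−B and R−G have pooled
mean identically zero — their mean cannot serve as a divisor. For such
structurally mean-free variables (detected as |mean| < 1e-6 × mean |v|) the
divisor falls back to the pooled mean magnitude, which is positive and
scale-appropriate. Downstream results are insensitive to this choice: rank
tests are invariant to any positive rescaling, and the PLS models autoscale
every column anyway. A related consequence is that the sign of group
differences in the *normalized* difference indices reflects relative
(log-scale) channel variation, which need not match the direction of the
raw R−B gap.

By default the normalizer is fit on the training split only and applied to
validation (`normalize_scope: train`), avoiding leakage; `all` reproduces
the simpler fit-on-everything variant.

Missing indices from zero denominators propagate as NaN (never ±inf); rows
with missing predictors are dropped before modeling with a logged count.

## Outcome models

**Threshold rule.** (R−B)/(R²+B²) ≥ 1.00 → dehisced, < 1.00 → healed. The
pipeline applies the cutoff to the *normalized* variable, whose population
mean is 1, so the rule reads "above the population average". It is
deliberately weak — a univariate baseline the multivariate models must
beat.

**PCA** of the autoscaled predictor matrix (SVD; constant columns dropped
with a warning) is used only for visualization of class structure.

**PLSDA.** PLS1 regression of the 0/1 outcome dummy on autoscaled
predictors, fitted by NIPALS with deflation; the regression vector is
b = W(PᵀW)⁻¹q and predictions ŷ = ȳ + X_scaled·b are thresholded at 0.5.
Autoscaling is the standard chemometrics choice for predictors with mixed
units (cm², days, years, unitless indices). The component count can be
fixed or chosen by stratified 10-fold cross-validated misclassification
(ties toward fewer components, capped at 10). At full rank PLS1 reproduces
ordinary least squares — one of the tested identities — and the
implementation is cross-checked against an independent NIPALS
implementation in the test suite.

**Sequential two-stage classifier.** Stage 1 fits delayed vs not-delayed on
all training rows; stage 2 fits healed vs dehisced on the rows whose true
class is not delayed (`route_by: truth`; routing stage 2's training set by
stage-1 predictions is available as `route_by: prediction`). At prediction,
stage-1 "delayed" becomes a final "healed"; everything else takes stage
2's call, so the final label space is {healed, dehisced} and a
predicted-delayed sample never reaches stage 2. The structural value of the
two stages is expressiveness: two sequential linear cuts form a piecewise
linear boundary that can isolate a class lying *between* the other two,
which no single linear discriminant can.

**Permutation test.** The observed score is the stratified cross-validated
accuracy of a model recipe on the true labels; each of n_perm (default 200)
permutations shuffles the labels with the seeded generator and re-runs the
identical recipe, and p = (1 + #{permuted ≥ observed}) / (1 + n_perm). The
+1 correction keeps p in (0, 1]; a permutation whose refit fails is retried
up to three times and then counted as ≥ observed (conservative). Under a
true null the test is calibrated: the suite measures a rejection rate of
0.03 at α = 0.05 over 200 null datasets with 99 permutations each.

**Split.** Stratified 75/25 by outcome class, seeded; per-class prevalence
in each side differs from the full data by at most one sample. Splitting is
at the image level, treating each debridement as an independent
measurement; grouping by wound or patient would be stricter and is left to
the caller by splitting on a per-wound table instead.

## The synthetic cohort generator

Wound-bed pixels follow a single-layer Beer-Lambert model:

I_c = gain_c · L_c · exp(−[(s·ε_HbO₂(c) + (1−s)·ε_Hb(c))·c_Hb + δ·(1−s)]·d) + ε

with s = StO₂, effective extinction coefficients at the three band centers
(R: 0.10/0.30, G: 5.00/5.30, B: 2.00/2.30 for HbO₂/Hb in scaled units),
path length d = 0.25, illumination L = (0.80, 0.92, 0.88), and a broadband
devitalized-tissue absorbance δ = 2.2 scaled by (1−s) that darkens every
channel of poorly oxygenated beds. Only the orderings are contractual —
ε_Hb(red) > ε_HbO₂(red), so R−B increases strictly with StO₂, and the
(1−s)-scaled broadband term, so (R−B)/(R²+B²) decreases strictly with StO₂
— not spectroscopic accuracy. Gaussian pixel noise (sd 0.012) is added
after the gain; wound beds are jittered ellipses over textured skin tone.

Cohorts are sampled hierarchically: 30 patients by default, ~1.8 wounds per
patient, ~5.5 debridements per wound (≈300 images), two hospitals with
different camera gains (70/30 weighting), wound-level outcomes at exact
largest-remainder proportions (healed 0.55, delayed 0.25, dehisced 0.20),
per-class StO₂ trajectories (healed 0.72 rising, delayed 0.58 slowly
rising, dehisced 0.45 falling; sd 0.06), closure days consistent with the
class definitions (delayed closes after day 21), covariates (wound area
~230 ± 120 cm², age ~34 ± 12), and artifact injection at 2% per type.
Child seeds are derived by stable hashing of (seed, patient, wound,
debridement), so cohorts are reproducible and individual images
re-renderable.

Two named departures from the default condition support testing:
`null_config` equalizes StO₂ and covariate distributions across classes
(no recoverable signal), and `delayed_confound_config` places dehisced
wounds *between* healed and delayed along every linear direction of
(spectra, days post-injury) — healed bright and closed early, delayed dark
and closed late, dehisced intermediate — the regime in which the two-stage
classifier holds a structural advantage over a single flat PLSDA (observed
in ≥ 18 of 20 seeded cohorts, mean accuracy gap ≈ +0.06).

What the generator does not emulate: photorealistic wound appearance, 3-D
geometry and specular shading, myoglobin, camera spectral response curves,
and any real covariance between covariates and spectra beyond the outcome
classes. Passing tests therefore demonstrate that the *pipeline* recovers
planted structure and controls overfitting, not that real wounds are
separable at these rates.

## Numerical and reporting choices

- FDR adjustment is Benjamini-Hochberg step-up; χ² is Pearson without
  continuity correction; the Mann-Whitney U uses the exact null
  distribution for n_x·n_y ≤ 400 without ties, otherwise the normal
  approximation with tie and continuity corrections.
- The DOR interval is Woolf (log scale, z = 1.96); with any zero cell the
  Haldane-Anscombe 0.5 correction is applied to all four cells when
  enabled, otherwise a zero cell is an explicit error.
- Printed percentages round half away from zero to one decimal. The
  positive class is always dehisced.
- All randomness flows from named seeds (cohort seed, split seed,
  permutation seed); fixed config + seed gives byte-identical CSV/JSON
  outputs, written atomically (temp file + rename).
- Test and acceptance problem sizes: cohorts of 6–30 patients at 32–128 px
  images, 20-seed comparisons, 200 null datasets × 99 permutations for the
  calibration check — sizes chosen to exercise every code path at
  desk-scale runtime (the full suite runs in well under a minute of
  compute-heavy testing).

## Known limitations

- The two normalization stages interact: group differences in normalized
  difference indices are relative-scale effects and can differ in sign
  from the raw channel gaps (see above). Interpretation of those two
  variables should lean on the raw versions.
- QC thresholds are calibrated to the generator, not to clinical imagery.
- Image-level splitting ignores within-wound correlation across
  debridements; per-wound or per-patient grouping would give more
  conservative validation estimates.
- The PLSDA decision threshold is fixed at 0.5 on the dummy scale;
  class-imbalance-aware (Bayesian) thresholds are out of scope.
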