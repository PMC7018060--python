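# Methods

## The artifact model

Beam hardening depresses measured CT numbers as the amount of absorbing
material in the scan plane grows.  Rather than model the physics
(polychromatic transport, sinogram correction), the package models the
*residual* artifact empirically, per scanner, as a log-linear function of a
subject-size index s:

    CT#(s) = B − A · ln(s)

B is the CT number the region would read at size index 1; A (HU per ln
unit) quantifies the artifact and grows with the density of the material
being measured.  The model is fit by ordinary least squares of ROI mean HU
on ln(s) over a calibration set of QCT-phantom scans spanning the cohort's
size range.  All logarithms in the package are natural logs.

Two size indices are implemented:

* **TSI** = (mean FOV HU − air HU) × FOV area(mm²) / 10⁷.  The FOV region is
  the reconstruction circle of the stated diameter centred in the matrix;
  pixels outside it are excluded from both the mean and the area.  Air HU
  defaults to −1024 (configurable; some scanners report −1000).  The 10⁷
  divisor puts small-primate slices in the 0–10 range.
* **CSA** (mm²): area of absorbing material, either from a hand-traced ROI
  or automatically (threshold HU > −400, morphological closing of radius 2
  pixels, hole filling — a reproducible stand-in for manual tracing).

The per-animal size index is the mean over the axial slices intersecting
the organ ROIs (three in the motivating protocol).

## Calibration workflow

`BeamHardeningCalibrator.fit` takes one row per (slice, phantom region):

1. per-region OLS fits of CT# = B − A·ln(s), A reported as the negated
   slope with its OLS standard error;
2. slope-homogeneity of the two regions that bracket soft tissue (0 and
   50 mg/ml calcium hydroxyapatite): the region × ln(s) interaction's Wald
   statistic (estimate/SE)² referred to **F(1, residual df)**.  The F (=
   squared t) reference is exact in the Gaussian linear model and converges
   to the conventional χ²₁ as n grows; at calibration-set sizes of ~18
   observations per region the χ²₁ reference is anticonservative (true
   level ≈ 0.06), so the exact reference is used.  α defaults to 0.05.
3. when pooling is accepted (or forced), a common-slope/separate-intercept
   model over the two regions; its negated shared slope is the correction
   coefficient **A**.  Soft tissue lies between those two regions' CT
   numbers, which is why their pooled slope is the right correction scale.
4. AIC comparison of candidate size indices using the full four-region
   model (region-specific intercepts *and* slopes, matching the per-region
   calibration curves).  AIC follows the Gaussian profile-likelihood
   convention n·(ln(2π·RSS/n) + 1) + 2k; the additive constant cancels in
   comparisons, which are all the package uses AIC for.

A is always estimated from the supplied phantom data, never hard-coded.
Per-slice observations are the default unit; per-animal averaging is the
caller's choice of input.

## The correction

    corrected HU = measured HU + A · ln(size indexᵢ / mean size index)

`SizeCorrector.fit` computes the cohort-mean size index over *distinct
animals* (the size index is an animal-level quantity); a fixed
`reference_mean` can be supplied for cross-study comparability.  Properties
that follow algebraically and are verified by test: the correction is the
identity for an animal of exactly average size; two scans of identical
tissue at different sizes whose measurements follow the artifact model with
the same A correct to identical values; under the matched generator the
cross-animal variance of corrected HU never exceeds that of measured HU.

The detectability argument uses an area-weighted mixture of HU range
midpoints: with kidney (20, 40) and collagen (75, 115), midpoints k = 30 and
c = 95, a collagen volume fraction f raises mean HU by 100·f·(c−k)/k percent
— linear in f, 10.83 % at f = 0.05.  Both ranges are configurable.

## Histology quantification

Trichrome blue-area fraction is measured in HSB space on the ImageJ-style
0–255 scale (standard RGB→HSV conversion).  The default blue window — hue
140–200, saturation ≥ 60, brightness ≥ 40 — separates the generator's blue
class from pink tissue and white background with margin; published
threshold values for real stains vary with batch and scanner, so every
bound is configurable and should be tuned on reference swatches before use
on real slides.  The hue window may wrap around the circle.  The
section-level value averages 3 cortical ROIs × 2 reads = 6 fractions.
Semiquantitative reader scores (two masked 0–4 reads, averaged) binarize to
"fibrotic" at mean ≥ 1.  Artery avoidance and cyst exclusion are
ROI-authoring concerns; the tool applies masks as given.

## Diagnostics

* **GEE logistic regression** of the fibrosis flag on corrected HU:
  binomial mean model, exchangeable working correlation over the two
  kidneys within an animal, cluster-robust (sandwich) SEs.  With zero
  estimated within-animal correlation it reproduces the independent
  logistic fit.  Perfect separation is detected (classes disjoint on the
  score) and flagged rather than hidden.
* **ROC**: cutoffs at midpoints between consecutive distinct scores plus
  ±∞; a kidney is positive iff its score strictly exceeds the cutoff (ties
  negative); AUC is the Mann–Whitney concordance probability with ties
  counted 1/2, identical to the trapezoidal area.  PPV/NPV are computed at
  the sample's observed prevalence.
* **Paired side test**: paired t on right-minus-left differences over
  animals with both sides known, used to justify pooling kidneys.
* **Method correlation**: both methods z-scored and stacked (one row per
  kidney × method); a linear mixed model with a fixed method effect and a
  random intercept per *kidney* (the unit both methods measure, nested in
  animal) gives the ICC var(kidney)/(var(kidney)+var(residual)) as the
  between-method correlation.  A kidney-level intercept was chosen over an
  animal-level one because the animal-only formulation either truncates two
  non-negative variance components at zero (large positive bias for truly
  uncorrelated methods) or, with a free 2×2 per-animal covariance, is
  unidentified when between-animal variance vanishes.  The estimate is 1
  for methods that agree exactly on every kidney and centred at 0 for
  independent methods; when each animal contributes one kidney it falls
  back to the textbook Pearson r.  Pearson r over kidneys is always
  reported alongside, and both the full-cohort and score > 0 subsets are
  supported.
* **Group comparison**: kidney values averaged within animal (animals are
  the independent units), then a Welch two-sample t-test.
* Unknown-side kidneys: a seeded helper keeps one randomly chosen scan per
  unknown-side animal, enabling the exclusion sensitivity analysis.

## Synthetic data

The generators define the study conditions under which every claim is
tested:

* **Phantom** (`PhantomSimConfig`): 4 regions with intercepts B = (60, 110,
  160, 260) HU and slopes A = (8, 9, 15, 24) HU/ln-unit rising with density;
  18 slices with TSI log-uniform on (2, 9) (the cohort's observed range);
  noise σ = 1 HU; 2 slices per animal.  CSA is proportional to TSI
  (4 500 mm² per TSI unit, a realistic small-primate magnitude) with
  multiplicative log-normal noise (σ = 0.25), so the HU bias is generated
  *through* ln(TSI) and CSA explains it only noisily — the setting in which
  the AIC comparison should, and does, select TSI.
* **Cohort** (`CohortSimConfig`): 10 total-body, 10 chest-only, 2 control
  animals with two kidneys each, mirroring the motivating study design;
  fibrosis scores are means of two integer 0–4 reads drawn around group
  means 2.0 / 0.5 / 0.0 (SD 0.8); true cortical HU = 30 + 8·score (healthy
  base inside the published 20–40 HU range); measured HU = true −
  A·ln(size/size₀) + N(0, 3 HU) with A = 8.5 and size₀ the configured
  size-distribution midpoint, so the generator and the corrector share the
  same normalization convention.  An optional `prevalence` parameter draws
  the fibrosis flag directly (Bernoulli) for prevalence-calibrated cohorts.
* **CT slices** (`SliceSimConfig`): 512² matrix, 320 mm FOV, elliptical
  body/organs over air; analytic TSI available in closed form, and raster
  vs analytic agreement is bounded by boundary-pixel discretization.
* **Trichrome** (`TrichromeSimConfig`): a smoothed random field thresholded
  at the exact count quantile gives patchy blue over pink tissue with a
  white border; the realized blue fraction equals round(f·N)/N exactly, and
  the class colours sit far enough from the threshold window that per-pixel
  jitter (±8) cannot cross it.

The beam-hardening artifact is injected at the *measurement* level as
−A·ln(size/size₀), not via x-ray physics.  That is exactly the form the
correction removes, so these simulations validate the statistical pipeline
— estimation, propagation, and diagnostics — not the physical adequacy of
the log-linear model for any particular scanner, which must be established
with that scanner's own phantom data.  Likewise the trichrome generator's
colour classes are cleanly separable by construction; real stains need
threshold tuning and may not admit any error-free window.

## Problem sizes and numerical choices

Simulation-based checks use 500 replicates for calibration bias and Wald
level, 200 for AIC model selection, 60 cohort seeds for the
corrected-vs-uncorrected win rates, a 2 000-kidney cohort for the null AUC,
and 100 images for histology recovery — sizes at which the Monte-Carlo
error is small against each acceptance band.  Polygon rasterization uses
the even-odd rule on voxel centres (0-based indices, centres at
index × spacing) so small hand counts replicate the tool exactly.  Ties at
a ROC cutoff are negative calls.  Degenerate inputs (empty ROIs, rank-
deficient calibration designs, single-class outcomes, non-positive size
indices) raise errors naming the offending object rather than returning
NaNs.

## Known limitations

* The log-linear artifact model is scanner-specific; coefficients do not
  transfer between scanners, and the package deliberately provides no
  default A.
* Cortex/kidney segmentation is out of scope: ROIs are ingested, not
  derived.
* The automatic CSA mode is a threshold heuristic; hand-traced ROIs
  override it.
* The mixed-model correlation reports one documented variance structure;
  with 22 animals, structure choice can move the estimate by a few
  hundredths (the Pearson companion estimate makes this visible).
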