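# renalqct

Subject-size-corrected quantitative CT biomarkers of renal fibrosis.

## The problem

Renal cortical fibrosis replaces parenchyma (≈ 20–40 HU on non-contrast CT)
with collagen-rich scar (tendon, mostly collagen and water, reads ≈ 75–115
HU).  An area-weighted mixture argument says a kidney that is 5 % fibrotic
by volume should read about 10 % higher in mean HU — comfortably above the
2–4 % coefficients of variation of quantitative CT.  The catch is beam
hardening: a polychromatic x-ray beam loses its soft photons in bigger
subjects, so the measured CT number of identical tissue *falls* as subject
size grows, and the size effect can swamp the fibrosis signal.

`renalqct` implements the full correction-and-evaluation workflow for
researchers doing quantitative CT in cohorts of varying body size (the
motivating use case is serial imaging of irradiated non-human primates
developing radiation nephropathy):

1. **Size index** (`renalqct.size_index`) — the *total signal index*
   TSI = (mean FOV HU − air HU) × FOV area / 10⁷, a per-slice surrogate for
   total absorbed x-ray signal computed from the scan itself, plus the
   competing tissue cross-sectional area (CSA).  Per-slice indices from the
   slices through the kidneys are averaged into an animal-level index.
2. **Calibration** (`renalqct.calibration`) — on a calcium-hydroxyapatite
   QCT phantom scanned alongside the subjects, each phantom region obeys

       CT# = B − A · ln(size index)

   `BeamHardeningCalibrator` fits this per region, Wald-tests slope
   homogeneity of the two regions bracketing soft tissue (0 and 50 mg/ml),
   pools them into a common slope **A**, and compares TSI vs CSA by AIC.
3. **Correction** (`renalqct.correction`) — `SizeCorrector` normalizes every
   kidney to the cohort-mean size:

       corrected HU = measured HU + A · ln(size indexᵢ / mean size index)

4. **Histology ground truth** (`renalqct.histology`) — blue-area fraction of
   Masson-trichrome sections by HSB thresholding (3 ROIs × 2 reads
   averaged), and binarization of 0–4 reader scores at mean ≥ 1.
5. **Diagnostics** (`renalqct.diagnostics`) — GEE logistic regression with
   per-animal clustering, empirical ROC with operating points (sensitivity,
   specificity, PPV/NPV at observed prevalence), paired left/right tests,
   exposure-group comparisons, and mixed-model method correlations.

`renalqct.synthetic` generates phantom observations, cohorts, CT slice
rasters and trichrome images with known ground truth, so the whole pipeline
is testable end to end without patient data.

## Worked example

```python
import numpy as np
from renalqct import (BeamHardeningCalibrator, SizeCorrector,
                      roc_analysis, predicted_ct_increase)
from renalqct.synthetic import (PhantomSimConfig, CohortSimConfig,
                                simulate_phantom_observations, simulate_cohort)

print(f"predicted HU increase at 5% fibrosis: {predicted_ct_increase(0.05):.2f}%")

rng = np.random.default_rng(0)
phantom = simulate_phantom_observations(PhantomSimConfig(), rng=rng)
cal = BeamHardeningCalibrator().fit(phantom)
print(f"pooled A = {cal.pooled_A_:.2f} HU per ln(TSI) unit")
print(f"P1/P2 slope-homogeneity p = {cal.slope_test_.p_value:.2f} -> pool: {cal.slope_test_.pool}")
print(f"AIC: TSI {cal.comparison_.aic_tsi:.1f} vs CSA {cal.comparison_.aic_csa:.1f} "
      f"-> size index: {cal.comparison_.selected}")

cohort = simulate_cohort(CohortSimConfig(), rng=rng)
corrected = SizeCorrector(A=cal.pooled_A_).fit(cohort).transform(cohort)
corrected["fibrotic"] = corrected["fibrosis_score"] >= 1
auc_c = roc_analysis(corrected).auc
auc_m = roc_analysis(corrected, score_col="measured_hu").auc
print(f"AUC, corrected HU: {auc_c:.2f}   uncorrected HU: {auc_m:.2f}")
```

prints

```
predicted HU increase at 5% fibrosis: 10.83%
pooled A = 8.67 HU per ln(TSI) unit
P1/P2 slope-homogeneity p = 0.12 -> pool: True
AIC: TSI 222.1 vs CSA 356.5 -> size index: tsi
AUC, corrected HU: 0.98   uncorrected HU: 0.96
```

Reading the output: the mixture prediction says 5 % fibrosis is detectable;
the phantom fit recovers the scanner's artifact slope (the generator's truth
is A ≈ 8–9 HU per ln unit) and finds the two soft-tissue phantom regions
poolable; TSI explains the size-dependent HU variation better than CSA
(lower AIC); and correcting HU for subject size improves discrimination of
fibrotic from non-fibrotic kidneys.

A `renalqct` command exposes the same workflow from the shell
(`renalqct simulate phantom|cohort|slice|trichrome`, `renalqct calibrate`,
`renalqct correct`, `renalqct diagnose`).

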