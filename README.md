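# maflim

Analysis pipeline for **multispectral autofluorescence lifetime imaging
(maFLIM) endoscopy** of the oral cavity: from raw time-resolved decay
datacubes to per-pixel metabolic biomarkers and automated discrimination
of dysplastic/cancerous from healthy tissue.

maFLIM records, at every image pixel, the fluorescence intensity decay
`y_λ(x, y, t)` in three emission bands chosen to preferentially capture
collagen (390 ± 20 nm), NADH (452 ± 22.5 nm) and FAD (>500 nm)
autofluorescence under 355 nm pulsed excitation. Because neoplastic
transformation alters both the composition (collagen breakdown, NADH/FAD
redox balance) and the decay kinetics of these fluorophores, a handful of
intensity and lifetime features per pixel carries diagnostic signal. This
package implements the full computer-aided-detection chain for such data
and a synthetic data generator so everything is testable without clinical
recordings.

## The model

The measured decay is the convolution of the tissue's fluorescence
impulse response (FIR) with the instrument response function (IRF):

    y_λ(t) = u_λ(t) * h_λ(t),   h_λ(t) = α_fast e^(−t/τ_fast) + α_slow e^(−t/τ_slow)

Lifetimes are estimated by nonlinear least-squares **iterative
reconvolution** (candidate FIRs convolved with the measured IRF and
compared to the data), with the amplitudes solved linearly at each step
(variable projection). The bi-exponential order is justified by checking
that a third component no longer reduces the fit MSE. Per pixel and band
the amplitude-weighted average lifetime is

    τ_avg = (α_f τ_f² + α_s τ_s²) / (α_f τ_f + α_s τ_s).

**21 features per pixel**: 3 normalized intensities `I_λ,n = I_λ / Σ I_λ`
(with `I_λ = ∫ y_λ dt`), 6 absolute-intensity ratios
(`I390/I452, I390/I500, I452/I500, (I452+I500)/I390, (I390+I500)/I452,
(I390+I452)/I500`), and `τ_fast, τ_slow, α_fast, τ_avg` per band.

**Classification**: LDA, QDA, linear SVM (C = 100) or logistic
regression at the pixel level yields a posterior probability map; the
image-level score is the Brier-like mean of squared pixel posteriors;
the image is called positive when the score reaches a threshold chosen
on the training ROC as the maximum-sensitivity point with
(1 − specificity) ≤ 30%. Features are chosen per cross-validation fold
by sequential forward search (≤3 features, maximizing training
image-level ROC-AUC) under a paired 7-fold subject-level CV, and a
SVM–QDA ensemble combines the spectral and time-resolved members through
a convex combination `w1·p_SVM + (1−w1)·p_QDA`, with `w1` grid-searched
in steps of 0.1.

## Worked example

```python
from maflim import (generate_cohort, dataset_records, cross_validate,
                    SPECTRAL_FEATURES, sensitivity, specificity)

dataset, scenes = generate_cohort(n_subjects=20, effect_size="strong", seed=11)
records = dataset_records(dataset, scenes)      # preprocess → fit → features
result = cross_validate(records, "SVM", SPECTRAL_FEATURES, k=7, seed=11)
print(f"sensitivity {sensitivity(result.confusion):.2f} "
      f"specificity {specificity(result.confusion):.2f} "
      f"ROC-AUC {result.auc:.2f}")
```

prints

```
sensitivity 0.95 specificity 0.90 ROC-AUC 0.98
```

i.e. on a 20-subject paired synthetic cohort whose lesion class shifts
the six reported biomarkers (`↓I390,n, ↑I452,n, ↓I390/I500, ↓τavg,390,
↓τfast,452, ↑αfast,452`) by 1.5 healthy-population standard deviations,
7-fold cross-validated whole-image classification recovers 19/20 lesions
while misclassifying 2/20 healthy images, with an image-level ROC-AUC of
0.98. On a null cohort (identical class distributions) the same pipeline
stays at chance (AUC ≈ 0.55).

The same workflow is scriptable from the shell:

```bash
maflim simulate --n 20 --effect strong --seed 11 --out cohort/
maflim cv --data cohort/ --model-kind SVM --pool spectral --seed 11 --out report.json
maflim evaluate --confusion confusion.csv
```

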