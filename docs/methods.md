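# Methods

This note records the scientific and numerical choices behind the
package, in the order the pipeline runs.

## Data model and container

A maFLIM image is a three-band time-resolved datacube
`decay[band](row, col, t)` with a shared time step `dt` (ns): 0.25 ns at
a 4 GS/s digitizer, 0.16 ns at 6.25 GS/s. Bands are fixed in the order
(390 ± 20 nm, 452 ± 22.5 nm, >500 nm), labelled `b390 / b452 / b500`;
the open-ended ">500 nm" band is subscripted 500 in feature names. Each
image is stored in one self-describing HDF5 container
(`/bands/{band}/decay`, `/irf/{band}`, `/mask/{valid,reason}`, root
attributes `dt_ns`, geometry and metadata); writes are atomic
(temp-file + rename). Coordinates are row-major and 0-based. No
vendor/acquisition format exists to follow, so the container is a
convention of this package, not a reconstruction of one.

## Preprocessing

Fixed order: background subtraction → saturation mask → 5×5 spatial
averaging → SNR mask → manual mask. Masks only grow along the chain.

* **Background**: the mean of the leading `baseline_window` (default 16)
  pre-pulse samples is subtracted per pixel and band. The synthetic IRF
  peaks at 5 ns so the default window (4 ns at 0.25 ns) stays pre-pulse.
* **Saturation**: a pixel is masked when its raw maximum over time and
  bands reaches `saturation_fraction` (default 0.98) of the digitizer
  full scale. The 0.98 default tolerates quantization at the rail; the
  threshold comparison is inclusive (≥ masks).
* **Spatial averaging** (order 5×5) trades spatial resolution for
  temporal SNR. Edges and masked neighbours are handled by
  shrink-to-valid: the mean runs over the remaining kernel members, so
  no signal is invented at the field-of-view rim. Pixels with no valid
  neighbour keep their trace.
* **SNR mask**: per pixel `SNR_dB = 20·log10(peak / baseline-noise σ)`,
  taken over the *worst* band, keep iff ≥ 15 dB. The worst-band rule is
  the conservative choice where a per-band vs combined definition was
  open; zero noise yields +inf (kept). Peak ≤ 0 yields −inf (masked).
* **Manual masks** (tooth regions etc.) are supplied as JSON region
  lists (half-open rectangles or polygons), never interactively, so
  runs are headless and reproducible. Idempotent by construction.
* **Sampling harmonization**: training- and testing-style instruments
  digitize at 4 vs 6.25 GS/s; decays and IRF are linearly interpolated
  onto the coarser grid (downsampling only — upsampling would fabricate
  temporal information). Changing the grid also changes the
  rectangle-rule convolution quadrature bias by a fraction of a sample;
  the optional IRF time-shift fit parameter absorbs this (see below).

## Lifetime fitting

The measured decay is modelled as the causal discrete convolution
(rectangle rule, scaled by `dt`, truncated to the record) of the sampled
multi-exponential FIR with the measured IRF. Estimation is nonlinear
least squares by iterative reconvolution with **variable projection**:
for fixed lifetimes the amplitudes are linear and solved by nonnegative
least squares, so the trust-region search runs over lifetimes only.

* Bounds τ ∈ [0.05, 20] ns (plausible for 355 nm-excited tissue
  fluorophores); amplitudes ≥ 0, reported normalized
  (α_fast + α_slow = 1) with the absolute scale absorbed first;
  components sorted so τ_fast ≤ τ_slow.
* Multi-start from three fixed seeds (τ_f, τ_s) ∈ {(0.3, 2), (0.5, 4),
  (1, 6)} ns avoids local minima without randomness; the best-MSE start
  wins. Convergence: relative cost change < 1e-8 or 500 evaluations.
  Non-convergence is flagged (`converged=False`, best-so-far
  parameters), never raised, so one bad pixel cannot abort an image.
* **Model order**: the smallest order whose MSE the next order fails to
  improve by >1% (relative) is selected; noiseless fits that already sit
  at numerical zero (MSE < 1e−20 × signal power) short-circuit, since
  comparisons below roundoff are meaningless. The pipeline default is
  order 2 without re-running selection.
* **Time shift** (`FitConfig.fit_shift`, default off): an optional
  fractional-sample IRF displacement (±0.5 ns, linear interpolation)
  fitted alongside the lifetimes. Whether a shift was fitted in the
  original instruments is unknown, hence off by default; it matters for
  cross-sampling-rate work, where it brings the resampling-induced
  lifetime bias from ~3% to <1%.
* **Batch fitting** (`fit_image`): a coarse dictionary of IRF-convolved
  exponentials (24 log-spaced lifetimes, all pairs) is evaluated for all
  pixels at once by linear least squares; the per-pixel winner seeds the
  same variable-projection refinement `fit_biexp` uses. This is purely a
  warm start — the objective and bounds are identical — and keeps a
  16×16×3-band image around two seconds.
* τ_avg uses the closed form (α_f τ_f² + α_s τ_s²)/(α_f τ_f + α_s τ_s),
  the exact integral of t·h(t)/∫h(t) for a bi-exponential; tests verify
  it against dense numerical integration.

**Accuracy**: fitting single decays (Gaussian IRF FWHM 1 ns,
dt = 0.25 ns) recovers noiseless parameters to <1%. At a flat 30 dB
peak-SNR the single-decay lifetime scatter is ~10% median — the fit
residual equals the noise floor (MSE/σ² ≈ 0.98), i.e. the estimator is
at its variance limit, not stuck in local minima. Over decays spanning
noiseless to 30 dB the median relative lifetime error is ~1-2% (<5%)
and τ_avg ~<1% (<3%); τ_avg is far better determined than the
individual components because their errors compensate. In images, 5×5
averaging raises the effective SNR well above the single-trace figure.

## Features

21 per-pixel features in a fixed canonical order (required for
reproducible feature selection): 3 normalized intensities, 6 intensity
ratios, then τ_fast/τ_slow/α_fast/τ_avg per band. α_slow is not a
feature (redundant: 1 − α_fast). Absolute intensities `I_λ` are
trapezoid-rule integrals over the full post-subtraction record
(integration window exposed in config; gating was left unspecified and
full-record is the simplest defensible choice) and serve only as
intermediates — they depend on gain and working distance, while the
ratios and normalized intensities are gain-invariant and the
time-resolved features are invariant to intensity scaling entirely.
Ratios are computed after the full preprocessing chain. Pixels with an
undefined feature (zero intensity sum or ratio denominator, failed fit)
are invalidated rather than carrying NaN into classification.

## Classification

Pixel labels inherit the image's histopathology label (lesion image →
positive, contralateral healthy → negative) — an explicit label-noise
assumption, since only image-level truth exists. Features are z-scored
with training statistics. scikit-learn fits LDA, QDA, linear SVM
(L2-regularized, C = 100, `LinearSVC`) and (effectively unpenalized)
logistic regression; fitted parameters are extracted into a plain JSON
form and posteriors evaluated from those parameters, making serialized
models reproduce predictions bit-for-bit. The SVM margin is calibrated
to a posterior by a Platt-style sigmoid fitted on training decision
values. QDA class covariances receive a 1e−6 trace-scaled ridge when
near-singular (small feature sets can degenerate), with a warning; when
a covariance is exactly rank-deficient the class moments are taken
directly and ridged. Class priors are empirical (≈0.5 under the paired
design).

Image score = mean of squared pixel posteriors over valid pixels
(masked pixels excluded). Threshold: over candidate cuts (midpoints of
sorted unique training scores plus sentinels), the maximum-sensitivity
point subject to FPR ≤ 30%; ties break toward lower FPR, then higher
threshold; classification is score ≥ threshold (inclusive). If nothing
feasible classifies a positive correctly, the feasible threshold is
returned with a warning rather than an error.

## Model selection

Folds partition *subjects* (pairs never split): shuffle by seed, assign
round-robin — for 34 subjects and k = 7 this yields six folds of 5
subjects (10 images) and one of 4 (8 images). Per fold, sequential
forward search grows ≤3 features from one pool (9 spectral-only or 12
time-resolved-only), maximizing training *image-level* ROC-AUC (the
thresholds and ROC analysis all operate on image scores); the final set
is the greedy prefix with the largest AUC, ties favouring the smaller
set (parsimony) and, between candidate features, the canonical
inventory order. All training-only statistics (standardization, SFS,
thresholds) are recorded per fold with the image ids they touched, so
leakage is checkable after the fact.

The ensemble weight w1 is grid-searched over {0, 0.1, …, 1}: each
candidate gets a full k-fold CV with both members retrained per fold on
their fixed top-3 most-frequent features (no further selection) and the
threshold optimized on the weighted-map scores. The returned w1
maximizes F1, ties broken by higher sensitivity then lower w1. Note the
threshold re-optimization makes many weights equivalent when one member
dominates; the tie-break then picks the smallest such weight. Final
models are retrained on the full training set, thresholds re-optimized
there, then locked (serialized, immutable).

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), F1 = TP/(TP+(FP+FN)/2);
printed as half-up integer percent and 2-decimal F1 to match reporting
conventions. Confusion matrices carry optional per-grade rows
(MiD/MoD/HiD/SCC vs Healthy) that must sum to the binary totals.
ROC-AUC uses the Mann–Whitney rank form (ties half credit), identical
to the trapezoidal area under the empirical ROC curve — the test suite
verifies both identities and agreement with scikit-learn. Undefined
metrics raise a typed error instead of returning silent zeros, because
small synthetic folds can degenerate.

## Synthetic data generator

The generator emulates the *study conditions*, not optical physics: per
pixel, bi-exponential kinetic parameters are drawn from spatially
correlated Gaussian fields (smoothed white noise, correlation length
2 px — this is what makes 5×5 averaging meaningful), convolved with a
unit-area Gaussian IRF (FWHM 1 ns, matching the 1 ns excitation pulse),
scaled to a per-band peak amplitude, offset by a DC level, and corrupted
by Gaussian noise with variance `floor²·(1 + 0.3·signal/peak)` — a
Gaussian approximation to shot noise adequate for analog-sampled FLIM —
with the floor set so the peak-to-baseline-noise SNR hits the 30 dB
target. Saturated pixels (amplitude driven past the rail and clipped)
and near-dark rectangular "tooth" regions are injected with configurable
probabilities; all ground truth (parameter maps, masks, noise levels) is
recorded, and scenes are byte-identical given (params, seed).

Healthy-class defaults: band peak amplitudes (1.0, 0.75, 0.55) for
(390, 452, >500) nm — collagen-dominant, as in oral mucosa; α_fast
(0.60, 0.55, 0.50) ± 0.05; τ_fast (0.8, 1.0, 0.9) ± 0.12 ns; τ_slow
(4.5, 4.0, 3.8) ± 0.4 ns. These are field-plausible round numbers; only
the *directions* of disease effects are established, so lesion classes
shift six biomarkers (↓I390 amplitude, ↑I452 amplitude, ↓τ_fast,452,
↑α_fast,452, ↓τ_slow,390 and ↓τ_fast,390 for ↓τ_avg,390) by 0.5 (or
1.5) healthy-population standard deviations for the moderate (strong)
effect size. A null effect uses identical distributions. Cohorts are
paired: each subject's lesion and healthy scene share subject-level
random offsets in amplitude and kinetics, mimicking inter-subject
variability that pairing controls for; histopathology grades are drawn
with the SCC-dominant mix of the emulated training cohort.

**Problem sizes.** Single scenes default to 64×64×256 samples at
0.25 ns (resolving τ_fast ≈ 0.5 ns over a 64 ns record). Cohorts default
to 16×16×160 scenes — at the image level the Brier-like score averages
hundreds of pixels, so discrimination power saturates well below full
resolution and the end-to-end suites stay desk-scale. The acceptance
run uses 20-pair cohorts.

**What passing says — and does not.** The generator's decays are truly
bi-exponential, its noise Gaussian, its classes Gaussian-shifted; real
tissue has fluorophore mixtures, photobleaching, motion, specular
artifacts and pixel-level label error, none of which are modelled. Green
pipelines here demonstrate correctness of the machinery and calibration
under known truth (null cohorts stay at chance), not clinical
performance; the published patient-level results are not reproducible
without the clinical recordings, which have no public accession.

## Visualization

Posterior overlays blend the probability map (red scale) over the total
intensity map (grey scale): `R = (1−p)·g + p·(0.25 + 0.75·g)`,
`G = B = (1−p)·g`, keeping anatomy visible beneath high posteriors
(red floor 0.25 so lesions stay visible over dark tissue); p = 0
reproduces the grayscale exactly, masked pixels render background only.
Posterior maps also export as 16-bit grayscale TIFF.

## Known limitations

* Single-pixel fits at ≤30 dB carry ~10% lifetime scatter (variance
  limit); interpretation should lean on τ_avg and on spatially averaged
  maps.
* The SFS is greedy and capped at 3 features by design; it will miss
  complementary pairs whose singles are weak.
* Pixel-label noise from image-level annotation biases posteriors
  toward the image mean; the Brier-like image score is robust to this,
  individual pixel posteriors are not.
* The generator's class shifts are axis-aligned and Gaussian; it cannot
  probe robustness to covariance differences beyond what QDA exploits.
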