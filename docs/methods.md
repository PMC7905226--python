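# Methods

`gliorad` implements a radiomics → machine-learning workflow for predicting a
binary molecular status (the motivating application: TERT-promoter mutation in
WHO grade II gliomas) from 3D image volumes with delineated regions of
interest. This note records the model, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Preprocessing

Intensities are z-score standardized over the in-mask voxels only (sample SD,
n − 1 denominator); whole-volume statistics would make the features depend on
how much background a segmentation protocol includes. Texture analysis then
discretizes the standardized in-mask intensities into `Ng` equal-width gray
levels spanning the in-mask range (maximum maps to the top level). The default
`Ng = 32` is a common radiomics compromise between histogram resolution and
co-occurrence-matrix sparsity; it is exposed in `ExtractionConfig` because no
single value is canonical. Spatial registration/resampling is deliberately
not performed: interpolation resamples texture, so features are computed on
the native anisotropic grid (default spacing 0.65 × 0.65 × 5 mm) with
spacing-aware shape math. The DICE coefficient 2|A∩B|/(|A|+|B|) with a 5 %
disagreement flag is provided for mask-agreement checks between raters.

## The 431-feature bank

Per sequence the bank is 14 first-order + 8 shape + 33 texture + 376 wavelet
features (8 sub-bands × (14 + 33)); three sequences concatenate to 1,293.
Names follow `<sequence>_<group>_<feature>[_<sub-band 1..8>]`.

* **First-order (14)**: energy, entropy, kurtosis, maximum, mean, mean
  absolute deviation, median, minimum, range, RMS, skewness, SD, uniformity,
  variance. Entropy/uniformity are computed on the discretized histogram
  (log base 2); skewness/kurtosis use population moments with kurtosis on
  the Pearson convention (Gaussian = 3); SD/variance use n − 1. A constant
  region returns entropy 0, uniformity 1 and sentinel 0 for the undefined
  moment ratios.
* **Shape (8)**: volume (voxel count × voxel volume), surface area,
  surface-to-volume ratio, sphericity, spherical disproportion, compactness 1
  and 2, maximum 3D diameter (max pairwise distance between surface voxel
  centers, mm). The surface area comes from a marching-cubes triangulation of
  the padded binary mask with physical spacing, and is the *single* source
  for all area-derived features so they stay mutually consistent; a
  voxel-face-counting surface is available for strictly digital geometry.
* **Texture (22 GLCM + 11 GLRLM)**: matrices at offset distance 1 along the
  13 unique 3D directions, features averaged over directions. Co-occurrence
  matrices are symmetrized and normalized per direction; pairs crossing the
  mask boundary are ignored, and directions with no valid pair (e.g.
  through-plane on a single-slice ROI) are excluded from the average. Runs
  are maximal same-level segments truncated at the mask boundary; per
  direction, run lengths conserve the in-mask voxel count. Formula
  conventions follow the classic Haralick / run-length radiomics lineage,
  including the historical quirk that Sum Variance centers on Sum Entropy;
  correlation-type features on a zero-variance matrix return a sentinel 0
  with a warning rather than NaN so downstream selection never sees missing
  values. Every formula is verified against a brute-force enumeration oracle
  (tolerance 1e−10) in the test suite.
* **Wavelet (376)**: a single-level separable 3D decomposition into the 8
  low/high sub-bands (fixed order LLL, LLH, LHL, LHH, HLL, HLH, HHL, HHH,
  indexed 1..8 in feature names). The default transform is *undecimated*
  (stationary, basis `coif1`, configurable), so sub-bands retain the grid
  shape and the original ROI mask pools sub-band voxels directly — the only
  construction under which per-sub-band texture is well defined. A decimated
  orthonormal reference mode exists for the Parseval energy check. First-order
  and texture features are recomputed per sub-band with a fresh equal-width
  discretization of the sub-band's in-mask values.

## Nested cross-validation

Outer 10-fold stratified CV estimates generalization; everything fitted —
standardization means/SDs, elastic-net selection, SVM hyperparameters, Platt
coefficients — derives from each outer fold's training partition alone, and
inner folds refit their own standardization. Stratification by outcome is
used because a ~93:71 imbalance can otherwise produce degenerate inner folds.

**Selection.** Elastic net with mixing weight α on the grid 0, 0.1, …, 1.0
(α = 0 is pure ridge and selects every column) and penalty λ along a
per-α logarithmic path of 30 points from the activation threshold
max|xᵀy|/(nα) down by 10⁻³. A fixed 0–1 λ grid would be solver-scale
dependent, so λ is data-driven while α carries the printed 0–1 grid. The
(α, λ) pair minimizes inner-CV Gaussian deviance (validation MSE on the 0/1
labels); the default criterion is minimum-plus-one-SE: at the winning α, the
largest λ whose mean deviance stays within one standard error of the minimum
(the sparsest admissible model). If the optimum selects nothing, the model is
refitted just below the activation threshold, where exactly the top-correlated
feature enters — this keeps null-data selections at one or two features
instead of an arbitrary handful, and is logged loudly. Features with non-zero
coefficients are the fold's selection; those selected in ≥ 9 of 10 outer
folds form the stability set.

**Classifier.** A linear soft-margin SVM whose box constraint C and kernel
scale s (the divisor applied to inputs before the kernel) are tuned on the
7-point grid 10⁻¹…10³ (step 10^(2/3)) by inner-CV misclassification loss,
ties broken toward smaller C then smaller s. Decision values are mapped to
posterior probabilities with Platt's sigmoid p = 1/(1 + exp(A·f + B)), fitted
per outer fold on training decision values by the numerically stable
Newton iteration with Platt's smoothed targets; A < 0, so the posterior is
strictly increasing in the decision value.

Pooling the held-out posteriors yields exactly one out-of-fold score per
subject — the construction consistent with a single cohort-level ROC curve
and per-subject posterior plots.

## Evaluation

AUC uses trapezoidal/Mann–Whitney tie handling. The operating point maximizes
sensitivity + specificity over all empirical cutoffs (ties → higher
specificity, then lower threshold). Confusion metrics report precision as
undefined (not 0) when no positive prediction exists. Confidence intervals
are 95 % percentile bootstrap over class-stratified case resamples (default
2,000, seed-controlled); stratification keeps both classes in every resample.
Association checks: point-biserial correlation (Pearson with 0/1 labels,
t-transform p-value) and an unpaired equal-variance t-test of posteriors by
class. Subgroup reports restrict the pooled posteriors to subgroup members at
the cohort-level threshold; when the minority class falls below 10 % the ROC
is flagged unreliable and the precision–recall metrics are the primary
summary (with 74 positives / 5 negatives and an all-positive predictor these
give the closed forms precision = 74/79 ≈ 0.9367 and F1 = 2·74/153 ≈ 0.9673).

## Synthetic data

Clinical cohorts for this problem are not publicly deposited, so the package
ships generators whose defaults define the benchmark conditions:

* **Phantoms**: ellipsoidal lesions (radii uniform in 6–12 mm, randomized
  independently of class, so shape carries no signal) on a 64 × 64 × 16 grid
  at 0.65 × 0.65 × 5 mm spacing, white-noise background (SD 0.2). Intra-lesion
  intensity is a Gaussian-smoothed noise field; class 1 scales the field's
  correlation length (base 1.5 mm) and SD (base 1.0) by 1 + texture_effect.
  Smoothed noise with a class-dependent kernel is the minimal mechanism that
  both co-occurrence and run-length features detect; `texture_effect = 0`
  makes the class distributions identical by construction. `texture_effect
  = 2` (a 3× autocorrelation-length ratio) is the strong-signal recovery
  condition.
* **Tabular fixtures**: Gaussian matrices at the study's dimensions
  (164 × 1,293, prevalence 93/164) with a known informative subset shifted by
  a configurable number of SDs — used for fast selection-recovery and
  permutation-null replicates.
* **Rosters**: subject tables whose exclusion flags (age < 18, missing
  mutation assay, pretreatment, missing preoperative MRI) are assigned to
  disjoint records in that priority order, so sequential filtering equals
  plain subtraction (275 − 26 − 11 − 8 − 66 = 164).

What phantom results do **not** show: the generators mimic neither MRI
contrast physics, bias fields, scanner artifacts, partial-volume effects nor
the correlation structure of real tumor texture. Passing recovery tests
demonstrates that the pipeline detects a known class-conditional texture
signal without leakage — not that any particular clinical accuracy is
attainable.

## Problem sizes and replicate counts

The shipped test suite runs the permutation null at 20 replicates and signal
recovery at 20 seeds on 164 × 1,293 tables, and one end-to-end phantom cohort
of 100 subjects × 3 sequences, using reduced (but fixed) α/λ/SVM grids for
replicated runs; package defaults keep the full grids. The acceptance script
uses 8 permutation replicates and 1,000 bootstrap draws. These sizes were
chosen once as a desk-scale benchmark; the statistical thresholds
(null AUC within 0.5 ± 2·SE, recovery AUC > 0.8, ≥ 5/10 informative features
stable) were fixed before the benchmarks were run.

## Known limitations

* Only GLCM/GLRLM texture families are implemented (by design — the bank is
  a fixed 431-feature roster); no GLSZM/NGTDM/LoG/LBP.
* The elastic net is Gaussian-family on 0/1 labels, not binomial; for
  selection purposes the two agree closely at these sample sizes, and the
  Gaussian path solver is what makes nested CV tractable at d = 1,293.
* Undecimated sub-band features on small ROIs inherit boundary effects from
  the symmetric padding of odd-sized grids.
* Marching-cubes surface area is mesh-resolution biased for very small ROIs
  (single-digit voxel counts); the face-counting surface is exact for digital
  geometry but overestimates smooth surfaces.
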