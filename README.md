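# gliorad

Radiomics feature extraction and nested cross-validated linear-SVM modelling
of binary molecular status from 3D medical images.

## The problem

In diffuse gliomas, molecular markers such as a TERT-promoter mutation guide
prognosis and surgical strategy, but their determination requires tissue.
Radiomics offers a non-invasive alternative: mine preoperative MRI for large
banks of engineered features (intensity, shape, texture, wavelet-filtered)
inside the delineated tumor, then train a classifier to predict the marker.
`gliorad` is a tested, reusable implementation of that workflow for
researchers in quantitative medical imaging:

* a **431-feature-per-sequence bank**: 14 first-order statistics, 8 shape
  features, 33 texture features (22 gray-level co-occurrence + 11 run-length,
  averaged over the 13 unique 3D directions at distance 1), and 376 wavelet
  features (14 + 33 recomputed on each of the 8 stationary-wavelet sub-bands);
  three sequences (T1, T2, contrast-enhanced T1) concatenate to 1,293
  features;
* **nested 10-fold cross-validation**: per outer fold, elastic-net feature
  selection (mixing weight α ∈ {0, 0.1, …, 1}, penalty λ on a data-driven log
  path, inner 10-fold CV with a one-standard-error rule) followed by a linear
  SVM tuned over box constraint and kernel scale grids 10⁻¹…10³, with Platt
  scaling of decision values to posterior probabilities — all fitted strictly
  inside the training partition;
* **stability selection**: features selected in ≥ 9 of the 10 outer folds;
* **evaluation** on pooled out-of-fold posteriors: ROC/AUC,
  Youden-optimal operating point, precision–recall/F1, percentile-bootstrap
  95 % CIs, point-biserial correlation, group t-tests, molecular-subgroup
  reports and misclassification breakdowns.

Because clinical cohorts for this task are not publicly deposited, the
package includes a synthetic module: texture-contrast phantom cohorts
(ellipsoidal lesions whose intra-lesion spatial autocorrelation and variance
differ by class), fast tabular fixtures with known informative features, and
cohort rosters reproducing a realistic retrospective exclusion flow
(275 − 26 − 11 − 8 − 66 = 164). See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
import numpy as np
from gliorad import (PhantomSpec, generate_phantom_cohort, extract_cohort,
                     EnetConfig, SvmConfig, run_nested_cv, stability_count,
                     evaluate_model)

# a 100-subject phantom cohort whose classes differ in intra-lesion texture
spec = PhantomSpec(n_subjects=100, texture_effect=2.0, seed=11)
volumes, masks, labels = generate_phantom_cohort(spec)
table = extract_cohort(list(zip(volumes, masks)), labels)   # 100 x 1294
print(table.shape)

result = run_nested_cv(
    table,
    enet_cfg=EnetConfig(alpha_grid=(0.1, 0.5, 1.0), n_lambdas=20, inner_folds=5),
    svm_cfg=SvmConfig(box_constraint_grid=(0.1, 10.0, 1000.0),
                      kernel_scale_grid=(0.46, 10.0, 215.4), inner_folds=5),
    seed=11,
)
report = evaluate_model(result.pooled_posteriors, result.labels, with_ci=False)
print(f"AUC {report.auc:.3f}  accuracy {report.accuracy:.3f}")
print([name for name, _ in stability_count(result)][:5])
```

printed:

```
(100, 1294)
AUC 1.000  accuracy 1.000
['CE-T1WI_FirstOrder_Mean Absolute Deviation_3',
 'CE-T1WI_FirstOrder_Mean Absolute Deviation_5',
 'CE-T1WI_FirstOrder_Minimum_2', 'CE-T1WI_FirstOrder_Range_2',
 'CE-T1WI_GLCM_Cluster Prominence_2']
```

With `texture_effect=2.0` the two classes differ threefold in intra-lesion
autocorrelation length, so the pipeline separates them perfectly; the stable
features are texture and wavelet-texture metrics, not shape (shape carries no
class signal by construction). With `texture_effect=0.0` the classes are
identical and the pooled AUC falls to chance (~0.5).

A command-line front end wraps the same functions:

```bash
gliorad simulate --spec spec.yaml --out cohort/ --seed 1
gliorad extract --image cohort/S000_T2WI.nii.gz --mask cohort/S000_mask.nii.gz \
    --sequence-tag T2WI --out features.csv
gliorad crossval --features features_all.csv --label-col label --seed 1 --out result.json
gliorad evaluate --result result.json --out report.json --plots figures/
```

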