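"""ROC / precision–recall evaluation of pooled out-of-fold posteriors.

All metrics are computed on the pooled out-of-fold posterior probabilities
(one score per subject), which is the construction consistent with a single
cohort-level ROC curve and per-subject posterior plots.  The positive class
is the mutant genotype throughout.  Confidence intervals are percentile
bootstrap over stratified case resamples (default 2,000 draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

__all__ = [
    "EvalReport",
    "roc_auc",
    "optimal_threshold",
    "pr_metrics",
    "bootstrap_ci",
    "point_biserial",
    "compare_groups",
    "subgroup_eval",
    "misclassification_summary",
    "evaluate_model",
]


def _as_arrays(posteriors, labels) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(posteriors, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("posteriors and labels must align")
    return p, y


def roc_auc(posteriors, labels) -> tuple[float, pd.DataFrame]:
    """AUC with the ROC curve; ties get half credit (Mann–Whitney equivalence)."""
    p, y = _as_arrays(posteriors, labels)
    if np.unique(y).size < 2:
        raise ValueError("ROC needs both classes")
    fpr, tpr, thr = roc_curve(y, p)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return float(roc_auc_score(y, p)), curve


def optimal_threshold(posteriors, labels) -> tuple[float, float, float]:
    """Operating point maximizing sensitivity + specificity (Youden).

    Candidate cutoffs are the observed scores plus one above the maximum
    (predict positive when posterior >= threshold).  Ties prefer the higher
    specificity, then the lower threshold.  Returns
    (threshold, sensitivity, specificity).
    """
    p, y = _as_arrays(posteriors, labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold search needs both classes")
    candidates = np.unique(p)
    candidates = np.append(candidates, candidates[-1] + 1.0)
    best = None
    for t in sorted(candidates):
        pred = p >= t
        sens = int((pred & (y == 1)).sum()) / n_pos
        spec = int((~pred & (y == 0)).sum()) / n_neg
        key = (sens + spec, spec, -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t, sens, spec = best
    return float(t), float(sens), float(spec)


def pr_metrics(
    posteriors, labels, threshold: float
) -> tuple[dict[str, float | None], pd.DataFrame]:
    """Confusion-table metrics at a fixed posterior cutoff, plus the P–R curve.

    With no positive predictions precision is undefined and reported as
    ``None``, and F1 is omitted alongside it.
    """
    p, y = _as_arrays(posteriors, labels)
    pred = p >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    metrics = {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": (tp + tn) / len(y),
        "sensitivity": recall,
        "specificity": tn / (tn + fp) if (tn + fp) > 0 else None,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }
    if np.unique(y).size == 2:
        prec_c, rec_c, thr_c = precision_recall_curve(y, p)
        curve = pd.DataFrame(
            {"precision": prec_c[:-1], "recall": rec_c[:-1], "threshold": thr_c}
        )
    else:
        curve = pd.DataFrame(columns=["precision", "recall", "threshold"])
    return metrics, curve


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    posteriors,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% percentile interval of a metric over stratified case resamples.

    Resampling is stratified by class (each class resampled with replacement
    within itself), so every resample keeps both classes; a resample on
    which the metric fails is redrawn.
    """
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    p, y = _as_arrays(posteriors, labels)
    rng = np.random.default_rng(seed)
    idx_by_class = [np.flatnonzero(y == c) for c in np.unique(y)]
    values = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(100):
            idx = np.concatenate(
                [rng.choice(ix, size=ix.size, replace=True) for ix in idx_by_class]
            )
            try:
                values[b] = metric(p[idx], y[idx])
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("bootstrap resample kept failing the metric")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def point_biserial(labels, posteriors) -> tuple[float, float]:
    """Point-biserial correlation between 0/1 labels and posteriors.

    Equals the Pearson correlation with labels coded 0/1; the p-value comes
    from the t transform with n − 2 degrees of freedom.
    """
    p, y = _as_arrays(posteriors, labels)
    if np.unique(y).size < 2:
        raise ValueError("point-biserial needs both classes")
    if np.ptp(p) == 0:
        raise ValueError("constant posteriors have no correlation")
    r, pval = stats.pointbiserialr(y, p)
    return float(r), float(pval)


def compare_groups(posteriors, labels) -> dict[str, float]:
    """Unpaired two-sample t-test of posteriors between the true classes."""
    p, y = _as_arrays(posteriors, labels)
    g1, g0 = p[y == 1], p[y == 0]
    if g1.size < 2 or g0.size < 2:
        raise ValueError("each group needs at least 2 members")
    t, pval = stats.ttest_ind(g1, g0, equal_var=True)
    return {
        "t": float(t),
        "p_value": float(pval),
        "mean_mutant": float(g1.mean()),
        "sd_mutant": float(g1.std(ddof=1)),
        "mean_wildtype": float(g0.mean()),
        "sd_wildtype": float(g0.std(ddof=1)),
        "significant": bool(pval < 0.05),
    }


@dataclass
class EvalReport:
    """Cohort-level performance summary on pooled out-of-fold posteriors."""

    positive_class: str = "pTERT mutant"
    n: int = 0
    auc: float | None = None
    threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    ci_95: dict[str, tuple[float, float]] = dc_field(default_factory=dict)
    r_pb: float | None = None
    r_pb_p: float | None = None
    t_test: dict[str, float] | None = None
    roc_unreliable: bool = False
    roc_error: str | None = None
    subgroups: dict[str, "EvalReport"] = dc_field(default_factory=dict)
    misclassified_indices: list[int] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("subgroups",)
        }
        out["subgroups"] = {k: v.to_dict() for k, v in self.subgroups.items()}
        return out


#: minority-class fraction below which the ROC is flagged unreliable and the
#: precision–recall view is the primary summary
IMBALANCE_FLAG_FRACTION = 0.10


def evaluate_model(
    posteriors,
    labels,
    threshold: float | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    with_ci: bool = True,
) -> EvalReport:
    """Full evaluation at the Youden-optimal (or supplied) threshold."""
    p, y = _as_arrays(posteriors, labels)
    report = EvalReport(n=len(y))
    classes = np.unique(y)
    minority = min((y == c).mean() for c in classes) if classes.size == 2 else 0.0
    try:
        report.auc, _ = roc_auc(p, y)
        report.roc_unreliable = minority < IMBALANCE_FLAG_FRACTION
    except ValueError as e:
        report.roc_error = str(e)
        report.roc_unreliable = True
    if threshold is None and classes.size == 2:
        threshold, _, _ = optimal_threshold(p, y)
    if threshold is not None:
        report.threshold = float(threshold)
        metrics, _ = pr_metrics(p, y, threshold)
        for key in ("sensitivity", "specificity", "accuracy", "precision", "recall", "f1"):
            setattr(report, key, metrics[key])
        report.misclassified_indices = np.flatnonzero(
            (p >= threshold).astype(int) != y
        ).tolist()
    if classes.size == 2 and np.ptp(p) > 0:
        report.r_pb, report.r_pb_p = point_biserial(y, p)
        if min((y == c).sum() for c in classes) >= 2:
            report.t_test = compare_groups(p, y)
    if with_ci and classes.size == 2:
        t = report.threshold

        def metric_fns() -> dict[str, Callable]:
            def at_threshold(name):
                def fn(pp, yy):
                    m, _ = pr_metrics(pp, yy, t)
                    if m[name] is None:
                        raise ValueError(f"{name} undefined on resample")
                    return m[name]

                return fn

            fns = {"auc": lambda pp, yy: roc_auc(pp, yy)[0]}
            for name in ("sensitivity", "specificity", "accuracy", "precision", "f1"):
                fns[name] = at_threshold(name)
            return fns

        for name, fn in metric_fns().items():
            if name == "auc" and report.auc is None:
                continue
            try:
                report.ci_95[name] = bootstrap_ci(fn, p, y, n_boot=n_boot, seed=seed)
            except (ValueError, RuntimeError):
                pass
        if report.f1 is not None and "f1" in report.ci_95:
            report.ci_95["recall"] = report.ci_95.get("sensitivity", (None, None))
    return report


def subgroup_eval(
    posteriors,
    labels,
    covariate: pd.Series | np.ndarray,
    threshold: float,
    n_boot: int = 500,
    seed: int = 0,
    with_ci: bool = False,
) -> dict[str, EvalReport]:
    """Per-level evaluation of a molecular covariate (e.g. IDH, 1p/19q).

    Metrics are restricted to subgroup members' pooled posteriors, at the
    cohort-level threshold.  Heavily imbalanced subgroups get their ROC
    flagged unreliable, with the precision–recall metrics as the primary
    summary; a single-class subgroup records the ROC error and still
    reports P–R metrics.
    """
    p, y = _as_arrays(posteriors, labels)
    cov = np.asarray(covariate)
    if cov.shape[0] != p.shape[0]:
        raise ValueError("covariate must align with posteriors")
    out: dict[str, EvalReport] = {}
    for level in pd.unique(cov):
        members = cov == level
        if not members.any():
            raise ValueError(f"empty subgroup {level!r}")
        out[str(level)] = evaluate_model(
            p[members],
            y[members],
            threshold=threshold,
            n_boot=n_boot,
            seed=seed,
            with_ci=with_ci,
        )
    return out


def misclassification_summary(
    posteriors,
    labels,
    threshold: float,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Count misclassified subjects by covariate level.

    Returns a tidy frame (covariate, level, count, percent) where percent is
    the share of all misclassified subjects at that covariate's levels, so
    percentages sum to 100 within each covariate.
    """
    p, y = _as_arrays(posteriors, labels)
    wrong = (p >= threshold).astype(int) != y
    n_wrong = int(wrong.sum())
    rows = []
    for col in covariates.columns:
        for level, cnt in covariates.loc[wrong, col].value_counts().items():
            rows.append(
                {
                    "covariate": col,
                    "level": level,
                    "count": int(cnt),
                    "percent": 100.0 * cnt / n_wrong if n_wrong else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["covariate", "level", "count", "percent"])
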