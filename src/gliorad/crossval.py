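"""Nested 10-fold cross-validation with elastic-net selection and linear SVM.

Per outer fold, the full modelling pipeline — feature standardization,
elastic-net feature selection, SVM hyperparameter tuning and Platt
calibration — is fitted on the nine training folds only (with its own inner
10-fold CV), then applied once to the held-out fold.  Pooling the held-out
posterior probabilities over the 10 outer folds yields exactly one
out-of-fold score per subject, on which cohort-level ROC / precision–recall
metrics are computed.

The elastic net mixes the LASSO and ridge penalties with weight ``alpha``
(the mixing grid runs 0..1 in steps of 0.1; ``alpha = 0`` is pure ridge and
selects every column) at strength ``lambda`` taken along a data-driven
logarithmic path, with the (alpha, lambda) pair chosen by inner-CV deviance
under a minimum or minimum-plus-one-SE criterion.  Features with non-zero
coefficients at the optimum are the fold's selection; features selected in
at least 9 of the 10 outer folds form the stability set.

The classifier is a soft-margin SVM with a linear kernel; its box constraint
C and kernel scale (the divisor applied to the inputs) are tuned on a 7-point
logarithmic grid ``10^-1 .. 10^3`` by inner-CV misclassification loss.
Posterior probabilities are obtained from SVM decision values by Platt's
sigmoid, fitted per outer fold on training-fold decision values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "EnetConfig",
    "SvmConfig",
    "FoldResult",
    "NestedCvResult",
    "make_folds",
    "enet_select",
    "svm_tune_train",
    "fit_platt",
    "apply_platt",
    "posterior_from_decision",
    "run_nested_cv",
    "stability_count",
]

#: 7-point log grid 10^-1 .. 10^3 (step 10^(2/3)): 0.1, 0.464, 2.15, 10, 46.4, 215.4, 1000
DEFAULT_SVM_GRID = tuple(np.logspace(-1, 3, 7))


@dataclass(frozen=True)
class EnetConfig:
    """Elastic-net selection settings.

    ``alpha_grid`` is the LASSO/ridge mixing weight grid; ``lambda`` runs
    along a per-alpha logarithmic path from the smallest value that zeroes
    every coefficient down by ``lambda_min_ratio``.
    """

    alpha_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
    n_lambdas: int = 30
    lambda_min_ratio: float = 1e-3
    criterion: str = "1se"  # "min" or "1se"
    inner_folds: int = 10

    def __post_init__(self) -> None:
        if len(self.alpha_grid) == 0:
            raise ValueError("alpha grid must be non-empty")
        if self.criterion not in ("min", "1se"):
            raise ValueError("criterion must be 'min' or '1se'")


@dataclass(frozen=True)
class SvmConfig:
    """Linear-SVM tuning settings (box constraint C and kernel scale grids)."""

    box_constraint_grid: tuple[float, ...] = DEFAULT_SVM_GRID
    kernel_scale_grid: tuple[float, ...] = DEFAULT_SVM_GRID
    inner_folds: int = 10

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.box_constraint_grid) or any(
            s <= 0 for s in self.kernel_scale_grid
        ):
            raise ValueError("SVM grids must be positive")


@dataclass
class FoldResult:
    """Everything fitted in one outer fold, for leakage audits and reports."""

    fold: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    selected_features: list[str]
    alpha: float
    lam: float
    box_constraint: float
    kernel_scale: float
    platt_a: float
    platt_b: float
    test_decisions: np.ndarray
    test_posteriors: np.ndarray


@dataclass
class NestedCvResult:
    """Pooled outcome of a nested cross-validation run."""

    folds: list[FoldResult]
    pooled_posteriors: np.ndarray
    pooled_decisions: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    stability_counts: dict[str, int] = field(default_factory=dict)
    k: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "folds": [
                {
                    "fold": f.fold,
                    "selected_features": f.selected_features,
                    "alpha": f.alpha,
                    "lambda": f.lam,
                    "box_constraint": f.box_constraint,
                    "kernel_scale": f.kernel_scale,
                    "test_ids": f.test_indices.tolist(),
                    "posteriors": f.test_posteriors.tolist(),
                }
                for f in self.folds
            ],
            "stability": sorted(
                self.stability_counts.items(), key=lambda kv: (-kv[1], kv[0])
            ),
            "pooled_posteriors": self.pooled_posteriors.tolist(),
            "labels": self.labels.tolist(),
        }


def make_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: array of fold ids in 0..k-1, one per subject."""
    labels = np.asarray(labels)
    if k == labels.shape[0]:  # leave-one-out: singleton folds need no strata
        return np.arange(k)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.shape[0], dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros_like(labels), labels)):
        assignment[test_idx] = fold
    return assignment


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _lambda_path(xs: np.ndarray, yc: np.ndarray, alpha: float, cfg: EnetConfig) -> np.ndarray:
    n = xs.shape[0]
    a = max(alpha, 1e-3)  # pure-ridge path anchored at the near-LASSO scale
    lam_max = np.abs(xs.T @ yc).max() / (n * a)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambdas)


def _ridge_path_coefs(xs: np.ndarray, yc: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Closed-form ridge coefficients for every penalty via one SVD.

    Matches the sklearn elastic-net objective at l1_ratio=0:
    1/(2n)||y - Xw||^2 + (lam/2)||w||^2  =>  w = (X'X/n + lam I)^+ X'y/n.
    """
    n = xs.shape[0]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    uty = u.T @ yc
    coefs = np.empty((xs.shape[1], lams.size))
    for j, lam in enumerate(lams):
        shrink = s / (s**2 + n * lam)
        coefs[:, j] = vt.T @ (shrink * uty)
    return coefs


def _path_coefs(
    xs: np.ndarray, yc: np.ndarray, alpha: float, lams: np.ndarray
) -> np.ndarray:
    """Coefficient path (d × n_lambdas) at one mixing weight."""
    if alpha == 0.0:
        return _ridge_path_coefs(xs, yc, lams)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = enet_path(
            xs, yc, l1_ratio=alpha, alphas=lams, max_iter=2000, tol=1e-4
        )
    return coefs


def enet_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    cfg: EnetConfig | None = None,
    seed: int = 0,
) -> tuple[list[str], float, float]:
    """Elastic-net feature selection with inner-CV choice of (alpha, lambda).

    Features are standardized within every training partition (the inner
    folds re-fit their own means/SDs).  The Gaussian-family deviance
    (validation mean squared error on the 0/1 labels) drives the grid
    choice: the global minimum, or — under the one-SE criterion — the
    largest lambda at the winning alpha whose mean deviance stays within one
    standard error of that minimum.  Returns (selected names, alpha, lambda);
    when the optimum selects nothing, the fit falls back to the largest
    lambda on the winning alpha's path with at least one non-zero
    coefficient.
    """
    cfg = cfg or EnetConfig()
    y = np.asarray(labels, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("labels are constant; selection is undefined")
    x = features.to_numpy(dtype=float)
    names = list(features.columns)
    n = x.shape[0]

    mean, sd = _standardize_fit(x)
    xs_full = (x - mean) / sd
    yc_full = y - y.mean()
    paths = {a: _lambda_path(xs_full, yc_full, a, cfg) for a in cfg.alpha_grid}

    k_inner = min(cfg.inner_folds, int(np.bincount(y.astype(int)).min()))
    skf = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    n_alpha, n_lam = len(cfg.alpha_grid), cfg.n_lambdas
    errors = np.empty((n_alpha, n_lam, k_inner))
    for f, (tr, va) in enumerate(skf.split(x, y)):
        m_tr, s_tr = _standardize_fit(x[tr])
        xs_tr = (x[tr] - m_tr) / s_tr
        xs_va = (x[va] - m_tr) / s_tr
        y_tr_mean = y[tr].mean()
        yc_tr = y[tr] - y_tr_mean
        for ai, a in enumerate(cfg.alpha_grid):
            coefs = _path_coefs(xs_tr, yc_tr, a, paths[a])
            preds = xs_va @ coefs + y_tr_mean
            errors[ai, :, f] = ((y[va][:, None] - preds) ** 2).mean(axis=0)

    mean_err = errors.mean(axis=2)
    se_err = errors.std(axis=2, ddof=1) / np.sqrt(k_inner)
    ai_best, li_best = np.unravel_index(np.argmin(mean_err), mean_err.shape)
    if cfg.criterion == "1se":
        limit = mean_err[ai_best, li_best] + se_err[ai_best, li_best]
        # lambdas are stored largest-first: the first index within one SE is
        # the sparsest admissible model at the winning alpha
        li_best = int(np.argmax(mean_err[ai_best] <= limit))
    alpha = float(cfg.alpha_grid[ai_best])
    lam = float(paths[alpha][li_best])

    if alpha == 0.0:
        return names, alpha, lam  # ridge zeroes nothing

    coefs = _path_coefs(xs_full, yc_full, alpha, paths[alpha])
    nonzero = coefs[:, li_best] != 0
    if not nonzero.any():
        # largest lambda with >=1 active coefficient: just below the
        # activation threshold max|x_j' y| / (n alpha), where exactly the
        # top-correlated feature enters
        lam = 0.99 * float(np.abs(xs_full.T @ yc_full).max()) / (n * alpha)
        for _ in range(30):
            model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                               max_iter=2000, tol=1e-6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(xs_full, yc_full)
            nonzero = model.coef_ != 0
            if nonzero.any():
                break
            lam *= 0.9
        else:
            raise ValueError("elastic net selected no feature at any penalty")
        warnings.warn(
            f"empty selection at the CV optimum; fell back to lambda={lam:.4g}",
            stacklevel=2,
        )
    return [names[i] for i in np.flatnonzero(nonzero)], alpha, lam


@dataclass
class FittedSvm:
    """A tuned linear SVM: decision value f(x) = w · (x / kernel_scale) + b."""

    model: SVC
    box_constraint: float
    kernel_scale: float
    feature_names: list[str]

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        return self.model.decision_function(x / self.kernel_scale)

    @property
    def weights(self) -> np.ndarray:
        return self.model.coef_.ravel() / self.kernel_scale

    @property
    def bias(self) -> float:
        return float(self.model.intercept_[0])


def svm_tune_train(
    features: pd.DataFrame,
    labels: np.ndarray,
    cfg: SvmConfig | None = None,
    seed: int = 0,
) -> FittedSvm:
    """Grid-tune (box constraint, kernel scale) by inner-CV loss and refit.

    The kernel scale divides the inputs before the linear kernel is applied.
    Ties are broken toward the smallest box constraint, then the smallest
    kernel scale (grids are scanned in ascending order).
    """
    cfg = cfg or SvmConfig()
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.shape[1] == 0:
        raise ValueError("no features selected; cannot train SVM")
    k_inner = min(cfg.inner_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))

    best = None
    for c in sorted(cfg.box_constraint_grid):
        for s in sorted(cfg.kernel_scale_grid):
            xs = x / s
            n_err = 0
            for tr, va in splits:
                clf = SVC(kernel="linear", C=c)
                clf.fit(xs[tr], y[tr])
                n_err += int((clf.predict(xs[va]) != y[va]).sum())
            loss = n_err / x.shape[0]
            if best is None or loss < best[0] - 1e-12:
                best = (loss, c, s)
    _, c, s = best
    clf = SVC(kernel="linear", C=c)
    clf.fit(x / s, y)
    return FittedSvm(clf, float(c), float(s), list(features.columns))


def fit_platt(decisions: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Fit Platt's sigmoid p = 1 / (1 + exp(A f + B)) by regularized MLE.

    Targets are Platt's smoothed frequencies t+ = (N+ + 1)/(N+ + 2) and
    t- = 1/(N- + 2); the Newton iteration follows the numerically stable
    formulation of Lin, Lin & Weng (2007).  With the positive class at
    higher decision values the fitted A is negative, making the posterior
    strictly increasing in f.
    """
    f = np.asarray(decisions, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Platt calibration needs both classes")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(aa: float, bb: float) -> float:
        # F = sum log(1 + e^z) - (1 - t) z  with z = a f + b
        zz = aa * f + bb
        return float(np.sum(np.logaddexp(0.0, zz) - (1 - t) * zz))

    a, b = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))
    for _ in range(100):
        z = a * f + b
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        w = p * (1 - p)
        resid = t - p  # dF/dz
        g1 = float((resid * f).sum())
        g2 = float(resid.sum())
        if max(abs(g1), abs(g2)) < 1e-10:
            break
        h11 = float((w * f * f).sum()) + 1e-12
        h22 = float(w.sum()) + 1e-12
        h12 = float((w * f).sum())
        det = h11 * h22 - h12 * h12
        # Newton descent step: solve H s = -grad
        da = -(h22 * g1 - h12 * g2) / det
        db = -(-h12 * g1 + h11 * g2) / det
        base = objective(a, b)
        step = 1.0
        while step > 1e-10 and objective(a + step * da, b + step * db) > base + 1e-12:
            step /= 2
        a, b = a + step * da, b + step * db
    return float(a), float(b)


def apply_platt(decisions: np.ndarray, a: float, b: float) -> np.ndarray:
    z = a * np.asarray(decisions, dtype=float) + b
    return np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))


def posterior_from_decision(
    decisions: np.ndarray, calibration_labels: np.ndarray
) -> np.ndarray:
    """Fit Platt's sigmoid on (decisions, labels) and return the posteriors."""
    a, b = fit_platt(decisions, calibration_labels)
    return apply_platt(decisions, a, b)


def run_nested_cv(
    table: pd.DataFrame,
    label_col: str = "label",
    enet_cfg: EnetConfig | None = None,
    svm_cfg: SvmConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> NestedCvResult:
    """Run the full nested cross-validation pipeline on a feature table.

    Per outer fold: standardize(train) → elastic-net selection(train) →
    SVM grid tuning(train) → Platt calibration(train) → score(test).  Every
    quantity applied to a test subject derives exclusively from that fold's
    training partition.
    """
    enet_cfg = enet_cfg or EnetConfig()
    svm_cfg = svm_cfg or SvmConfig()
    features = table.drop(columns=[label_col])
    y = table[label_col].to_numpy(dtype=int)
    names = list(features.columns)
    x = features.to_numpy(dtype=float)
    n = x.shape[0]

    assignment = make_folds(y, k, seed)
    pooled_post = np.full(n, np.nan)
    pooled_dec = np.full(n, np.nan)
    folds: list[FoldResult] = []
    counts: dict[str, int] = {}
    for fold in range(k):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        inner_seed = (seed * 100003 + fold * 7919 + 1) % (2**31)

        x_tr = pd.DataFrame(x[train_idx], columns=names)
        selected, alpha, lam = enet_select(x_tr, y[train_idx], enet_cfg, inner_seed)
        for s in selected:
            counts[s] = counts.get(s, 0) + 1

        mean, sd = _standardize_fit(x[train_idx])
        xs_tr = pd.DataFrame((x[train_idx] - mean) / sd, columns=names)[selected]
        xs_te = pd.DataFrame((x[test_idx] - mean) / sd, columns=names)[selected]
        svm = svm_tune_train(xs_tr, y[train_idx], svm_cfg, inner_seed)

        dec_tr = svm.decision_values(xs_tr.to_numpy())
        a, b = fit_platt(dec_tr, y[train_idx])
        dec_te = svm.decision_values(xs_te.to_numpy())
        post_te = apply_platt(dec_te, a, b)
        pooled_post[test_idx] = post_te
        pooled_dec[test_idx] = dec_te
        folds.append(
            FoldResult(
                fold=fold,
                train_indices=train_idx,
                test_indices=test_idx,
                selected_features=selected,
                alpha=alpha,
                lam=lam,
                box_constraint=svm.box_constraint,
                kernel_scale=svm.kernel_scale,
                platt_a=a,
                platt_b=b,
                test_decisions=dec_te,
                test_posteriors=post_te,
            )
        )
    assert not np.isnan(pooled_post).any()
    return NestedCvResult(
        folds=folds,
        pooled_posteriors=pooled_post,
        pooled_decisions=pooled_dec,
        labels=y,
        feature_names=names,
        stability_counts=counts,
        k=k,
        seed=seed,
    )


def stability_count(
    result: NestedCvResult, threshold: int = 9
) -> list[tuple[str, int]]:
    """Features selected in at least ``threshold`` outer folds.

    Sorted by selection count (descending) then name.  The study convention
    is threshold 9 of 10 outer loops.
    """
    hits = [(n, c) for n, c in result.stability_counts.items() if c >= threshold]
    return sorted(hits, key=lambda kv: (-kv[1], kv[0]))
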