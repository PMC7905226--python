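"""Figure helpers: ROC curve, precision–recall curve, posterior violins."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import pr_metrics, roc_auc

__all__ = ["plot_roc", "plot_pr", "plot_posterior_violin"]


def plot_roc(posteriors, labels, path: str) -> None:
    auc, curve = roc_auc(posteriors, labels)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve["fpr"], curve["tpr"], lw=1.5, label=f"AUC = {auc:.4f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pr(posteriors, labels, path: str) -> None:
    _, curve = pr_metrics(posteriors, labels, 0.5)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve["recall"], curve["precision"], lw=1.5)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_posterior_violin(posteriors, labels, path: str) -> None:
    p = np.asarray(posteriors, dtype=float)
    y = np.asarray(labels, dtype=int)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.violinplot([p[y == 0], p[y == 1]], showmedians=True)
    ax.set_xticks([1, 2], labels=["wild-type", "mutant"])
    ax.set_ylabel("Posterior probability (mutant)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
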