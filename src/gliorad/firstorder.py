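"""First-order intensity statistics over the region of interest.

Fourteen distribution summaries of the in-mask voxel intensities.  Entropy
and uniformity are histogram features and are computed on the discretized
gray levels; everything else is computed on the raw (typically z-scored)
intensities.  Skewness and kurtosis use population moments, with kurtosis
reported on the Pearson convention (a Gaussian scores 3); variance and
standard deviation use the n-1 denominator.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["first_order_features", "FIRST_ORDER_NAMES"]

FIRST_ORDER_NAMES = (
    "Energy",
    "Entropy",
    "Kurtosis",
    "Maximum",
    "Mean",
    "Mean Absolute Deviation",
    "Median",
    "Minimum",
    "Range",
    "Root Mean Square",
    "Skewness",
    "Standard Deviation",
    "Uniformity",
    "Variance",
)


def first_order_features(
    values: np.ndarray, labels: np.ndarray | None = None, n_bins: int = 32
) -> dict[str, float]:
    """Compute the 14 first-order features of a set of in-mask intensities.

    Parameters
    ----------
    values
        In-mask voxel intensities (flat array).
    labels
        Optional discrete gray levels of the same voxels (values in 1..Ng),
        used for the histogram features Entropy and Uniformity.  When absent,
        an equal-width ``n_bins`` binning of ``values`` is used; a constant
        region occupies a single bin (entropy 0, uniformity 1).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty region: first-order features need >= 1 voxel")

    if labels is None:
        lo, hi = x.min(), x.max()
        if lo == hi:
            lab = np.ones(x.size, dtype=int)
            n_levels = 1
        else:
            lab = np.minimum(
                np.floor((x - lo) / (hi - lo) * n_bins).astype(int) + 1, n_bins
            )
            n_levels = n_bins
    else:
        lab = np.asarray(labels, dtype=int).ravel()
        n_levels = int(lab.max())
    p = np.bincount(lab, minlength=n_levels + 1)[1:].astype(float)
    p = p / p.sum()
    pz = p[p > 0]

    mean = float(x.mean())
    if x.size > 1 and x.std() > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        skew, kurt = 0.0, 0.0  # undefined for a constant region; sentinel
    var = float(x.var(ddof=1)) if x.size > 1 else 0.0
    return {
        "Energy": float((x**2).sum()),
        "Entropy": float(-(pz * np.log2(pz)).sum()),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Mean Absolute Deviation": float(np.abs(x - mean).mean()),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "Root Mean Square": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Standard Deviation": float(np.sqrt(var)),
        "Uniformity": float((p**2).sum()),
        "Variance": var,
    }
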