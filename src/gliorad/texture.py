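"""Gray-level co-occurrence (GLCM) and run-length (GLRLM) texture features.

Matrices are built at offset distance 1 along the 13 unique 3D directions
(offsets modulo sign), and every scalar feature is the unweighted average of
its per-direction values — the common 3D radiomics convention.  Feature
definitions follow the classic Haralick / run-length formulations used
throughout the radiomics literature; formulas are stated in each docstring
so they can be checked against a brute-force enumeration.

Only voxel pairs (respectively runs) that lie entirely inside the region of
interest contribute; pairs crossing the mask boundary are ignored and runs
are truncated at it.
"""

from __future__ import annotations

import warnings

import numpy as np

from .preprocess import DegenerateRegionError, DiscretizedVolume

__all__ = [
    "DIRECTIONS_13",
    "glcm_build",
    "glcm_features",
    "GLCM_FEATURE_NAMES",
    "glrlm_build",
    "glrlm_features",
    "GLRLM_FEATURE_NAMES",
]

#: the 13 unique 3D offsets (all 26 neighbors modulo sign)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

GLCM_FEATURE_NAMES = (
    "Autocorrelation",
    "Cluster Prominence",
    "Cluster Shade",
    "Cluster Tendency",
    "Contrast",
    "Correlation",
    "Difference Entropy",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity 1",
    "Homogeneity 2",
    "Informational Measure of Correlation 1",
    "Informational Measure of Correlation 2",
    "Inverse Difference Moment Normalized",
    "Inverse Difference Normalized",
    "Inverse Variance",
    "Maximum Probability",
    "Sum Average",
    "Sum Entropy",
    "Sum Variance",
    "Variance",
)

GLRLM_FEATURE_NAMES = (
    "Short Run Emphasis",
    "Long Run Emphasis",
    "Gray Level Non-uniformity",
    "Run Length Non-uniformity",
    "Run Percentage",
    "Low Gray Level Run Emphasis",
    "High Gray Level Run Emphasis",
    "Short Run Low Gray Level Emphasis",
    "Short Run High Gray Level Emphasis",
    "Long Run Low Gray Level Emphasis",
    "Long Run High Gray Level Emphasis",
)


def _shifted_views(arr: np.ndarray, offset: tuple[int, int, int]):
    """Return (source, destination) views of ``arr`` for a voxel offset."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(offset):
        if d > 0:
            src[ax] = slice(0, arr.shape[ax] - d)
            dst[ax] = slice(d, arr.shape[ax])
        elif d < 0:
            src[ax] = slice(-d, arr.shape[ax])
            dst[ax] = slice(0, arr.shape[ax] + d)
    return arr[tuple(src)], arr[tuple(dst)]


def glcm_build(
    d: DiscretizedVolume,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> list[np.ndarray]:
    """Build one symmetrized, normalized Ng×Ng co-occurrence matrix per direction.

    Entry (i, j) is the probability that a voxel of level i+1 has a voxel of
    level j+1 at the given offset, counting each pair in both orders so every
    matrix is symmetric and its entries sum to 1.
    """
    labels = d.labels
    ng = d.n_bins
    out: list[np.ndarray] = []
    any_pairs = False
    for direction in directions:
        offset = tuple(int(distance) * c for c in direction)
        a, b = _shifted_views(labels, offset)
        valid = (a > 0) & (b > 0)
        mat = np.zeros((ng, ng), dtype=float)
        if valid.any():
            any_pairs = True
            idx = (a[valid] - 1) * ng + (b[valid] - 1)
            counts = np.bincount(idx, minlength=ng * ng).reshape(ng, ng).astype(float)
            mat = counts + counts.T
            mat /= mat.sum()
        out.append(mat)
    if not any_pairs:
        raise DegenerateRegionError("no valid co-occurrence pairs in any direction")
    return out


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    if p.sum() == 0:
        # direction with no pairs: contribute neutral zeros
        return {k: 0.0 for k in GLCM_FEATURE_NAMES}
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu_x = float((i * px).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ks_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in ks_sum])
    ks_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in ks_diff])

    f: dict[str, float] = {}
    f["Autocorrelation"] = float((ii * jj * p).sum())
    cdev = ii + jj - 2.0 * mu_x
    f["Cluster Prominence"] = float((cdev**4 * p).sum())
    f["Cluster Shade"] = float((cdev**3 * p).sum())
    f["Cluster Tendency"] = float((cdev**2 * p).sum())
    f["Contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sigma_x > 0:
        f["Correlation"] = (f["Autocorrelation"] - mu_x * mu_x) / (sigma_x * sigma_x)
    else:
        # single occupied gray level: correlation undefined; sentinel 0
        warnings.warn(
            "zero marginal variance in GLCM; correlation-type features set to 0",
            stacklevel=3,
        )
        f["Correlation"] = 0.0
    f["Difference Entropy"] = _entropy2(p_diff)
    f["Dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    f["Energy"] = float((p**2).sum())
    hxy = _entropy2(p.ravel())
    f["Entropy"] = hxy
    f["Homogeneity 1"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    f["Homogeneity 2"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    # informational measures of correlation, in bits
    px_outer = np.outer(px, px)
    hx = _entropy2(px)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-np.nansum(np.where(p > 0, p * np.log2(px_outer), 0.0)))
    hxy2 = _entropy2(px_outer.ravel())
    if hx > 0:
        f["Informational Measure of Correlation 1"] = (hxy - hxy1) / hx
    else:
        f["Informational Measure of Correlation 1"] = 0.0
    f["Informational Measure of Correlation 2"] = float(
        np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))
    )
    f["Inverse Difference Moment Normalized"] = float(
        (p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()
    )
    f["Inverse Difference Normalized"] = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    off = ii != jj
    f["Inverse Variance"] = float((p[off] / (ii[off] - jj[off]) ** 2).sum())
    f["Maximum Probability"] = float(p.max())
    sa = float((ks_sum * p_sum).sum())
    f["Sum Average"] = sa
    se = _entropy2(p_sum)
    f["Sum Entropy"] = se
    # Haralick's original sum variance is centered on sum entropy, a quirk
    # preserved throughout the radiomics lineage this bank follows
    f["Sum Variance"] = float(((ks_sum - se) ** 2 * p_sum).sum())
    f["Variance"] = float(((ii - mu_x) ** 2 * p).sum())
    return f


def glcm_features(matrices: list[np.ndarray]) -> dict[str, float]:
    """22 Haralick-style features, each averaged over the per-direction matrices.

    Directions without a single valid voxel pair (e.g. through-plane offsets
    on a one-slice ROI) carry no texture information and are excluded from
    the average.
    """
    per_dir = [_glcm_features_single(m) for m in matrices if m.sum() > 0]
    if not per_dir:
        raise DegenerateRegionError("no direction has any co-occurrence pair")
    return {
        name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_FEATURE_NAMES
    }


def _positive_direction(labels: np.ndarray, direction: tuple[int, int, int]):
    """Flip axes so the direction has non-negative components."""
    arr = labels
    for ax, d in enumerate(direction):
        if d < 0:
            arr = np.flip(arr, axis=ax)
    pos = tuple(abs(d) for d in direction)
    return arr, pos


def _runs_along(labels: np.ndarray, direction: tuple[int, int, int]):
    """Vectorized maximal-run extraction along one (positive) 3D direction.

    Voxels are grouped into lines by the invariant coordinates
    ``c - t * direction`` where ``t`` is the coordinate along the first axis
    the direction moves in; sorting each line by ``t`` exposes runs as blocks
    of consecutive, equal labels.
    Returns (run_levels, run_lengths).
    """
    arr, d = _positive_direction(labels, direction)
    coords = np.argwhere(arr > 0)
    if coords.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    lead_axis = next(ax for ax in range(3) if d[ax])
    t = coords[:, lead_axis]
    keys = [coords[:, ax] - d[ax] * t for ax in range(3)]
    order = np.lexsort((t, *keys))
    t_s = t[order]
    keys_s = [k[order] for k in keys]
    lab_s = arr[tuple(coords[order].T)]

    n = lab_s.size
    new_run = np.ones(n, dtype=bool)
    if n > 1:
        same_line = np.ones(n - 1, dtype=bool)
        for k in keys_s:
            same_line &= k[1:] == k[:-1]
        contiguous = t_s[1:] == t_s[:-1] + 1
        same_label = lab_s[1:] == lab_s[:-1]
        new_run[1:] = ~(same_line & contiguous & same_label)
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, n))
    return lab_s[starts], lengths


def glrlm_build(
    d: DiscretizedVolume,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> list[np.ndarray]:
    """One Ng×Rmax run-length count matrix per direction.

    Entry (i, j) counts maximal runs of gray level i+1 with length j+1; runs
    are truncated at the mask boundary, so for every direction
    ``sum_j (j+1) * r[i, j]`` over all i equals the in-mask voxel count.
    """
    ng = d.n_bins
    n_voxels = int((d.labels > 0).sum())
    if n_voxels == 0:
        raise DegenerateRegionError("empty mask")
    rmax = max(d.labels.shape)
    out = []
    for direction in directions:
        levels, lengths = _runs_along(d.labels, direction)
        mat = np.zeros((ng, rmax), dtype=float)
        np.add.at(mat, (levels - 1, lengths - 1), 1.0)
        out.append(mat)
    return out


def _glrlm_features_single(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = r.sum()
    if nr == 0:
        return {k: 0.0 for k in GLRLM_FEATURE_NAMES}
    ng, rmax = r.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, rmax + 1)[None, :].astype(float)
    f = {
        "Short Run Emphasis": (r / j**2).sum() / nr,
        "Long Run Emphasis": (r * j**2).sum() / nr,
        "Gray Level Non-uniformity": (r.sum(axis=1) ** 2).sum() / nr,
        "Run Length Non-uniformity": (r.sum(axis=0) ** 2).sum() / nr,
        "Run Percentage": nr / n_voxels,
        "Low Gray Level Run Emphasis": (r / i**2).sum() / nr,
        "High Gray Level Run Emphasis": (r * i**2).sum() / nr,
        "Short Run Low Gray Level Emphasis": (r / (i**2 * j**2)).sum() / nr,
        "Short Run High Gray Level Emphasis": (r * i**2 / j**2).sum() / nr,
        "Long Run Low Gray Level Emphasis": (r * j**2 / i**2).sum() / nr,
        "Long Run High Gray Level Emphasis": (r * i**2 * j**2).sum() / nr,
    }
    return {k: float(v) for k, v in f.items()}


def glrlm_features(matrices: list[np.ndarray], n_voxels: int) -> dict[str, float]:
    """11 run-emphasis features, averaged over the per-direction matrices."""
    per_dir = [_glrlm_features_single(m, n_voxels) for m in matrices]
    return {
        name: float(np.mean([d[name] for d in per_dir]))
        for name in GLRLM_FEATURE_NAMES
    }
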