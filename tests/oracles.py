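"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit Python loops over voxels,
pairs and runs — and shares no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def naive_glcm(labels: np.ndarray, ng: int, offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix by explicit pair loops."""
    counts = np.zeros((ng, ng))
    nz, ny, nx = labels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = labels[z, y, x]
                if a == 0:
                    continue
                z2, y2, x2 = z + offset[0], y + offset[1], x + offset[2]
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                b = labels[z2, y2, x2]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def naive_glcm_features(p: np.ndarray) -> dict[str, float]:
    """The 22 co-occurrence features by direct double summation."""
    ng = p.shape[0]

    def rng():
        return range(1, ng + 1)

    px = [sum(p[i - 1, j - 1] for j in rng()) for i in rng()]
    mu = sum(i * px[i - 1] for i in rng())
    sigma2 = sum((i - mu) ** 2 * px[i - 1] for i in rng())
    sigma = math.sqrt(sigma2)

    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in rng():
        for j in rng():
            p_sum[i + j] += p[i - 1, j - 1]
            p_diff[abs(i - j)] += p[i - 1, j - 1]

    def h(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    f: dict[str, float] = {}
    f["Autocorrelation"] = sum(i * j * p[i - 1, j - 1] for i in rng() for j in rng())
    for name, power in [
        ("Cluster Tendency", 2),
        ("Cluster Shade", 3),
        ("Cluster Prominence", 4),
    ]:
        f[name] = sum(
            (i + j - 2 * mu) ** power * p[i - 1, j - 1] for i in rng() for j in rng()
        )
    f["Contrast"] = sum((i - j) ** 2 * p[i - 1, j - 1] for i in rng() for j in rng())
    f["Correlation"] = (
        (f["Autocorrelation"] - mu * mu) / sigma2 if sigma2 > 0 else 0.0
    )
    f["Difference Entropy"] = h(p_diff.values())
    f["Dissimilarity"] = sum(abs(i - j) * p[i - 1, j - 1] for i in rng() for j in rng())
    f["Energy"] = sum(p[i - 1, j - 1] ** 2 for i in rng() for j in rng())
    hxy = h(p.ravel())
    f["Entropy"] = hxy
    f["Homogeneity 1"] = sum(
        p[i - 1, j - 1] / (1 + abs(i - j)) for i in rng() for j in rng()
    )
    f["Homogeneity 2"] = sum(
        p[i - 1, j - 1] / (1 + (i - j) ** 2) for i in rng() for j in rng()
    )
    hx = h(px)
    hxy1 = -sum(
        p[i - 1, j - 1] * math.log2(px[i - 1] * px[j - 1])
        for i in rng()
        for j in rng()
        if p[i - 1, j - 1] > 0 and px[i - 1] * px[j - 1] > 0
    )
    hxy2 = h([px[i - 1] * px[j - 1] for i in rng() for j in rng()])
    f["Informational Measure of Correlation 1"] = (
        (hxy - hxy1) / hx if hx > 0 else 0.0
    )
    f["Informational Measure of Correlation 2"] = math.sqrt(
        max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))
    )
    f["Inverse Difference Moment Normalized"] = sum(
        p[i - 1, j - 1] / (1 + (i - j) ** 2 / ng**2) for i in rng() for j in rng()
    )
    f["Inverse Difference Normalized"] = sum(
        p[i - 1, j - 1] / (1 + abs(i - j) / ng) for i in rng() for j in rng()
    )
    f["Inverse Variance"] = sum(
        p[i - 1, j - 1] / (i - j) ** 2 for i in rng() for j in rng() if i != j
    )
    f["Maximum Probability"] = float(p.max())
    sa = sum(k * v for k, v in p_sum.items())
    f["Sum Average"] = sa
    se = h(p_sum.values())
    f["Sum Entropy"] = se
    f["Sum Variance"] = sum((k - se) ** 2 * v for k, v in p_sum.items())
    f["Variance"] = sum(
        (i - mu) ** 2 * p[i - 1, j - 1] for i in rng() for j in rng()
    )
    return f


def naive_runs(labels: np.ndarray, offset: tuple[int, int, int]):
    """All maximal in-mask runs along one direction, by explicit walking."""
    nz, ny, nx = labels.shape

    def inside(z, y, x):
        return 0 <= z < nz and 0 <= y < ny and 0 <= x < nx

    runs = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                lab = labels[z, y, x]
                if lab == 0:
                    continue
                pz, py, px_ = z - offset[0], y - offset[1], x - offset[2]
                if inside(pz, py, px_) and labels[pz, py, px_] == lab:
                    continue  # not a run start
                length = 1
                cz, cy, cx = z + offset[0], y + offset[1], x + offset[2]
                while inside(cz, cy, cx) and labels[cz, cy, cx] == lab:
                    length += 1
                    cz, cy, cx = cz + offset[0], cy + offset[1], cx + offset[2]
                runs.append((lab, length))
    return runs


def naive_glrlm(labels: np.ndarray, ng: int, rmax: int, offset) -> np.ndarray:
    mat = np.zeros((ng, rmax))
    for lab, length in naive_runs(labels, offset):
        mat[lab - 1, length - 1] += 1
    return mat


def naive_glrlm_features(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = r.sum()
    ng, rmax = r.shape
    f = {
        "Short Run Emphasis": 0.0,
        "Long Run Emphasis": 0.0,
        "Low Gray Level Run Emphasis": 0.0,
        "High Gray Level Run Emphasis": 0.0,
        "Short Run Low Gray Level Emphasis": 0.0,
        "Short Run High Gray Level Emphasis": 0.0,
        "Long Run Low Gray Level Emphasis": 0.0,
        "Long Run High Gray Level Emphasis": 0.0,
    }
    for i in range(1, ng + 1):
        for j in range(1, rmax + 1):
            v = r[i - 1, j - 1]
            f["Short Run Emphasis"] += v / j**2
            f["Long Run Emphasis"] += v * j**2
            f["Low Gray Level Run Emphasis"] += v / i**2
            f["High Gray Level Run Emphasis"] += v * i**2
            f["Short Run Low Gray Level Emphasis"] += v / (i**2 * j**2)
            f["Short Run High Gray Level Emphasis"] += v * i**2 / j**2
            f["Long Run Low Gray Level Emphasis"] += v * j**2 / i**2
            f["Long Run High Gray Level Emphasis"] += v * i**2 * j**2
    f = {k: v / nr for k, v in f.items()}
    f["Gray Level Non-uniformity"] = sum(
        sum(r[i, :]) ** 2 for i in range(ng)
    ) / nr
    f["Run Length Non-uniformity"] = sum(
        sum(r[:, j]) ** 2 for j in range(rmax)
    ) / nr
    f["Run Percentage"] = nr / n_voxels
    return f


def pair_count_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as (concordant + half-tied) positive-negative pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_youden(scores: np.ndarray, labels: np.ndarray):
    """Best (sens+spec) over every cutpoint, scanning candidates directly."""
    candidates = sorted(set(scores)) + [max(scores) + 1.0]
    best = None
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        key = (sens + spec, spec, -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]
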