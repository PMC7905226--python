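"""Synthetic phantom cohorts, tabular fixtures and cohort rosters.

The study cohort this package is designed around is not publicly deposited,
so pipeline behaviour is demonstrated on synthetic data with a controllable
class-conditional texture signal:

* **Phantom volumes** — ellipsoidal lesions on a noise background.  The two
  outcome classes differ only in the *intra-lesion texture*: class-1 lesions
  are filled with a spatially correlated Gaussian field whose correlation
  length and variance are scaled up by ``texture_effect`` relative to the
  class-0 baseline field.  Smoothed-noise fields are the minimal mechanism
  that both co-occurrence (autocorrelation, contrast) and run-length
  features respond to.  Lesion shape is randomized identically in both
  classes, so shape features carry no class signal by default.
* **Tabular fixtures** — Gaussian feature matrices with a known informative
  subset, for fast cross-validation and selection-recovery tests at the
  study's dimensions (164 subjects × 1,293 features).
* **Cohort rosters** — subject tables with exclusion flags reproducing the
  sequential inclusion arithmetic of a retrospective cohort
  (275 − 26 − 11 − 8 − 66 = 164).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import RoiMask, VolumeImage

__all__ = [
    "PhantomSpec",
    "generate_phantom_cohort",
    "generate_feature_table",
    "build_roster",
    "apply_exclusions",
    "STUDY_EXCLUSION_COUNTS",
]

#: the study cohort's printed inclusion/exclusion arithmetic
STUDY_EXCLUSION_COUNTS = {
    "total": 275,
    "under18": 26,
    "no_ptert": 11,
    "pretreated": 8,
    "no_mri": 66,
}

_SEQ_TAGS = ("T1WI", "T2WI", "CE-T1WI")


@dataclass(frozen=True)
class PhantomSpec:
    """Generating conditions of a phantom cohort.

    texture_effect
        Non-negative scalar: class-1 intra-lesion fields have correlation
        length and standard deviation scaled by ``1 + texture_effect``
        relative to class 0.  Zero means the two class-conditional
        generating distributions are identical.
    """

    n_subjects: int = 100
    class_balance: float = 0.5
    n_sequences: int = 3
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    voxel_spacing_mm: tuple[float, float, float] = (0.65, 0.65, 5.0)
    lesion_radius_range_mm: tuple[float, float] = (6.0, 12.0)
    texture_effect: float = 0.0
    #: correlation length (mm) of the class-0 intra-lesion field
    base_kernel_mm: float = 1.5
    #: standard deviation of the class-0 intra-lesion field
    base_field_sd: float = 1.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError("class_balance must lie in [0, 1]")
        if self.n_sequences not in (1, 2, 3):
            raise ValueError("n_sequences must be 1, 2 or 3")
        if self.texture_effect < 0:
            raise ValueError("texture_effect must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.lesion_radius_range_mm
        if not 0 < lo <= hi:
            raise ValueError("lesion_radius_range_mm must be a positive interval")
        extent = [n * s for n, s in zip(self.grid_shape, self.voxel_spacing_mm)]
        for ax, e in enumerate(extent):
            if 2.0 * hi > e:
                raise ValueError(
                    f"largest lesion radius {hi} mm does not fit axis {ax} "
                    f"(grid extent {e:.1f} mm)"
                )


def _smooth_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    kernel_mm: float,
    sd: float,
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to the target SD."""
    noise = rng.standard_normal(shape)
    sigma_vox = [kernel_mm / s for s in spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    f_sd = f.std()
    if f_sd > 0:
        f *= sd / f_sd
    return f


def _ellipsoid_mask(
    rng: np.random.Generator, spec: PhantomSpec
) -> np.ndarray:
    lo, hi = spec.lesion_radius_range_mm
    radii = rng.uniform(lo, hi, size=3)
    extent = np.array([n * s for n, s in zip(spec.grid_shape, spec.voxel_spacing_mm)])
    center = extent / 2 + rng.uniform(-0.05, 0.05, size=3) * extent
    grids = np.meshgrid(
        *[
            (np.arange(n) + 0.5) * s
            for n, s in zip(spec.grid_shape, spec.voxel_spacing_mm)
        ],
        indexing="ij",
    )
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d2 <= 1.0


def generate_phantom_cohort(
    spec: PhantomSpec,
) -> tuple[list[list[VolumeImage]], list[RoiMask], np.ndarray]:
    """Generate a phantom cohort: per-subject sequence sets, masks and labels.

    Deterministic given ``spec.seed``.  Each subject has a single ellipsoidal
    lesion mask shared across its sequences; intra-lesion intensities are
    class-conditional smoothed-noise fields, the background is white noise.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_subjects * spec.class_balance))
    labels = np.zeros(spec.n_subjects, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    scale = 1.0 + spec.texture_effect
    volumes: list[list[VolumeImage]] = []
    masks: list[RoiMask] = []
    for lab in labels:
        mask_arr = _ellipsoid_mask(rng, spec)
        masks.append(RoiMask(mask_arr))
        kernel = spec.base_kernel_mm * (scale if lab == 1 else 1.0)
        field_sd = spec.base_field_sd * (scale if lab == 1 else 1.0)
        seqs = []
        for tag in _SEQ_TAGS[: spec.n_sequences]:
            background = rng.standard_normal(spec.grid_shape) * spec.noise_sd
            lesion = _smooth_field(
                rng, spec.grid_shape, kernel, field_sd, spec.voxel_spacing_mm
            )
            vol = background
            vol[mask_arr] = 1.0 + lesion[mask_arr]  # lesion sits above background
            seqs.append(VolumeImage(vol, spec.voxel_spacing_mm, tag))
        volumes.append(seqs)
    return volumes, masks, labels


def generate_feature_table(
    n: int,
    d: int,
    n_informative: int,
    effect_size: float,
    seed: int,
    prevalence: float = 93 / 164,
) -> pd.DataFrame:
    """Gaussian feature table with a known informative subset.

    Informative columns (named ``inf_###``) have their class-1 mean shifted
    by ``effect_size`` standard deviations; the remaining columns
    (``noise_###``) are pure N(0, 1) noise.  Default prevalence matches the
    study cohort (93 mutant / 164).  Returns a DataFrame with a ``label``
    column.
    """
    if n_informative > d:
        raise ValueError("n_informative must not exceed d")
    if n < 4:
        raise ValueError("need n >= 4 subjects to stratify folds")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    labels[: int(round(n * prevalence))] = 1
    rng.shuffle(labels)
    x = rng.standard_normal((n, d))
    x[labels == 1, :n_informative] += effect_size
    names = [f"inf_{i:03d}" for i in range(n_informative)] + [
        f"noise_{i:04d}" for i in range(d - n_informative)
    ]
    table = pd.DataFrame(x, columns=names)
    table["label"] = labels
    return table


def build_roster(
    counts: dict[str, int] | None = None,
    ptert_mutant: int = 93,
    idh_mutant_frac: float = 141 / 164,
    codeleted_frac: float = 79 / 164,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a cohort roster with the requested exclusion-category sizes.

    ``counts`` carries ``total`` and the four exclusion categories
    (``under18``, ``no_ptert``, ``pretreated``, ``no_mri``).  Flags are
    assigned to *disjoint* records in the priority order
    age → pTERT availability → pretreatment → MRI availability, matching a
    sequential exclusion narrative so that the survivor count equals the
    plain subtraction.  Molecular labels are assigned to eligible records;
    ``ptert_mutant`` mutants are placed among the eligible survivors.
    """
    c = dict(STUDY_EXCLUSION_COUNTS if counts is None else counts)
    total = c["total"]
    cats = [
        ("under18", c.get("under18", 0)),
        ("no_ptert", c.get("no_ptert", 0)),
        ("pretreated", c.get("pretreated", 0)),
        ("no_mri", c.get("no_mri", 0)),
    ]
    if any(v < 0 for _, v in cats) or total < 0:
        raise ValueError("counts must be non-negative")
    if sum(v for _, v in cats) > total:
        raise ValueError("exclusion categories exceed the total")

    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"P{i:04d}" for i in range(total)],
            "age": rng.integers(20, 81, size=total),
            "has_ptert_result": True,
            "pretreated": False,
            "has_preop_mri": True,
        }
    )
    pos = 0
    for name, k in cats:
        idx = df.index[pos : pos + k]
        if name == "under18":
            df.loc[idx, "age"] = rng.integers(5, 18, size=k)
        elif name == "no_ptert":
            df.loc[idx, "has_ptert_result"] = False
        elif name == "pretreated":
            df.loc[idx, "pretreated"] = True
        elif name == "no_mri":
            df.loc[idx, "has_preop_mri"] = False
        pos += k

    eligible = df.index[pos:]
    n_elig = len(eligible)
    ptert = np.array(["wild-type"] * total, dtype=object)
    idh = np.array(["wild-type"] * total, dtype=object)
    codel = np.array(["non-codeleted"] * total, dtype=object)
    if n_elig:
        ptert[eligible[: min(ptert_mutant, n_elig)]] = "mutant"
        idh[rng.choice(eligible, size=int(round(idh_mutant_frac * n_elig)), replace=False)] = "mutant"
        codel[rng.choice(eligible, size=int(round(codeleted_frac * n_elig)), replace=False)] = "codeleted"
    df["ptert"] = ptert
    df["idh"] = idh
    df["codeletion_1p19q"] = codel
    # shuffle rows so flag categories are not positionally ordered
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return df


def apply_exclusions(roster: pd.DataFrame) -> pd.DataFrame:
    """Apply the four sequential exclusions and return the survivors.

    Removal order: age < 18, missing pTERT result, pretreated, missing
    preoperative MRI.  A record carrying several flags is removed exactly
    once (set semantics), so on disjoint-flag rosters the survivor count
    equals total minus the sum of category sizes.
    """
    out = roster
    out = out[out["age"] >= 18]
    out = out[out["has_ptert_result"]]
    out = out[~out["pretreated"]]
    out = out[out["has_preop_mri"]]
    return out.reset_index(drop=True)
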