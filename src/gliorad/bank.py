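"""Assembly of the 431-feature-per-sequence radiomics bank.

Per sequence the bank is:

* 14 first-order intensity statistics,
* 8 shape/size features of the ROI,
* 33 texture features (22 co-occurrence + 11 run-length) on the original
  (z-scored, discretized) volume,
* 376 wavelet features: the 14 first-order + 33 texture features recomputed
  on each of the 8 stationary-wavelet sub-bands (8 × 47).

14 + 8 + 33 + 376 = 431; three sequences concatenate to 1,293 features.
Names follow ``<sequence>_<group>_<feature>[_<sub-band index>]`` where the
trailing index 1..8 identifies the sub-band in the documented LLL..HHH
ordering.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .preprocess import (
    RoiMask,
    VolumeImage,
    discretize_safe,
    zscore_normalize,
)
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    glcm_build,
    glcm_features,
    glrlm_build,
    glrlm_features,
)
from .wavelet import SUBBAND_ORDER, wavelet_decompose

__all__ = [
    "ExtractionConfig",
    "extract_sequence",
    "extract_subject",
    "extract_cohort",
    "sequence_feature_names",
    "N_FEATURES_PER_SEQUENCE",
    "N_WAVELET_FEATURES",
    "N_TEXTURE_FEATURES",
]

N_FIRST_ORDER = len(FIRST_ORDER_NAMES)  # 14
N_SHAPE = len(SHAPE_NAMES)  # 8
N_TEXTURE_FEATURES = len(GLCM_FEATURE_NAMES) + len(GLRLM_FEATURE_NAMES)  # 33
N_WAVELET_FEATURES = len(SUBBAND_ORDER) * (N_FIRST_ORDER + N_TEXTURE_FEATURES)  # 376
N_FEATURES_PER_SEQUENCE = (
    N_FIRST_ORDER + N_SHAPE + N_TEXTURE_FEATURES + N_WAVELET_FEATURES
)  # 431


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the extraction pipeline.

    n_bins
        Gray levels for texture discretization (applied after z-scoring).
    glcm_distance
        Co-occurrence offset distance in voxels.
    wavelet
        PyWavelets basis for the sub-band decomposition.
    surface
        Shape surface-area algorithm, ``"mesh"`` or ``"faces"``.
    """

    n_bins: int = 32
    glcm_distance: int = 1
    wavelet: str = "coif1"
    surface: str = "mesh"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _intensity_texture_block(
    volume: np.ndarray,
    mask: RoiMask,
    spacing: tuple[float, float, float],
    cfg: ExtractionConfig,
) -> dict[str, float]:
    """First-order + GLCM + GLRLM features of one (sub-band) volume."""
    img = VolumeImage(volume, spacing, "T2WI")
    disc = discretize_safe(img, mask, cfg.n_bins)
    values = volume[mask.mask]
    labels = disc.labels[mask.mask]
    out: dict[str, float] = {}
    for name, v in first_order_features(values, labels).items():
        out[f"FirstOrder_{name}"] = v
    glcm = glcm_build(disc, distance=cfg.glcm_distance)
    for name, v in glcm_features(glcm).items():
        out[f"GLCM_{name}"] = v
    glrlm = glrlm_build(disc)
    for name, v in glrlm_features(glrlm, mask.n_voxels).items():
        out[f"GLRLM_{name}"] = v
    return out


def extract_sequence(
    image: VolumeImage, mask: RoiMask, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Extract the full 431-feature bank from one sequence.

    The volume is z-score standardized over the ROI first; texture features
    use an equal-width ``config.n_bins`` discretization of the standardized
    intensities, recomputed per wavelet sub-band.
    """
    cfg = config or ExtractionConfig()
    tag = image.sequence_tag
    z = zscore_normalize(image, mask)
    spacing = image.voxel_spacing_mm

    features: dict[str, float] = {}
    for name, v in _intensity_texture_block(z.intensities, mask, spacing, cfg).items():
        features[f"{tag}_{name}"] = v
    for name, v in shape_features(mask, spacing, surface=cfg.surface).items():
        features[f"{tag}_Shape_{name}"] = v
    subbands = wavelet_decompose(z, wavelet=cfg.wavelet, undecimated=True)
    for k, key in enumerate(SUBBAND_ORDER, start=1):
        block = _intensity_texture_block(subbands[key], mask, spacing, cfg)
        for name, v in block.items():
            features[f"{tag}_{name}_{k}"] = v
    assert len(features) == N_FEATURES_PER_SEQUENCE
    return features


def extract_subject(
    images: list[VolumeImage], mask: RoiMask, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Concatenate per-sequence banks for one subject (431 per sequence).

    All sequences must share the mask geometry and carry distinct tags.
    """
    tags = [im.sequence_tag for im in images]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate sequence tags: {tags}")
    out: dict[str, float] = {}
    for image in images:
        out.update(extract_sequence(image, mask, config))
    return out


def extract_cohort(
    subjects: list[tuple[list[VolumeImage], RoiMask]],
    labels: np.ndarray | list[int] | None = None,
    config: ExtractionConfig | None = None,
    subject_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Extract a FeatureTable (subjects × features) for a cohort.

    Returns a DataFrame with one row per subject; if ``labels`` is given a
    ``label`` column is appended.
    """
    rows = [extract_subject(images, mask, config) for images, mask in subjects]
    ids = subject_ids or [f"S{i:03d}" for i in range(len(rows))]
    table = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    if labels is not None:
        table["label"] = np.asarray(labels, dtype=int)
    return table


def sequence_feature_names(tag: str, config: ExtractionConfig | None = None) -> list[str]:
    """The 431 feature names of one sequence, in stable extraction order."""
    cfg = config or ExtractionConfig()
    names = [f"{tag}_FirstOrder_{n}" for n in FIRST_ORDER_NAMES]
    names += [f"{tag}_GLCM_{n}" for n in GLCM_FEATURE_NAMES]
    names += [f"{tag}_GLRLM_{n}" for n in GLRLM_FEATURE_NAMES]
    names += [f"{tag}_Shape_{n}" for n in SHAPE_NAMES]
    for k in range(1, len(SUBBAND_ORDER) + 1):
        names += [f"{tag}_FirstOrder_{n}_{k}" for n in FIRST_ORDER_NAMES]
        names += [f"{tag}_GLCM_{n}_{k}" for n in GLCM_FEATURE_NAMES]
        names += [f"{tag}_GLRLM_{n}_{k}" for n in GLRLM_FEATURE_NAMES]
    return names
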