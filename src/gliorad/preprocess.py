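"""Image/mask containers, intensity normalization and gray-level discretization.

Radiomics texture matrices operate on integer gray levels, so continuous MRI
intensities are first z-score standardized over the region of interest and
then binned into ``Ng`` equal-width levels.  Normalization statistics are
computed over in-mask voxels only: whole-volume statistics would depend on
how much background the segmentation protocol happens to include.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "RoiMask",
    "DiscretizedVolume",
    "DegenerateRegionError",
    "GeometryMismatchError",
    "zscore_normalize",
    "discretize",
    "dice",
    "load_volume",
    "load_mask",
    "save_volume",
]

SEQUENCE_TAGS = ("T1WI", "T2WI", "CE-T1WI")

#: masks disagreeing by more than this (1 - DICE) trigger arbitration
DICE_DISAGREEMENT_LIMIT = 0.05


class DegenerateRegionError(ValueError):
    """Raised when a region of interest cannot support the requested statistic."""


class GeometryMismatchError(ValueError):
    """Raised when an image and mask do not share shape or voxel spacing."""


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    intensities
        3D float array of voxel intensities.
    voxel_spacing_mm
        Physical edge lengths of a voxel, in mm, one per axis.
    sequence_tag
        Which MRI-like sequence this volume represents (``T1WI``, ``T2WI``
        or ``CE-T1WI``).
    """

    intensities: np.ndarray
    voxel_spacing_mm: tuple[float, float, float] = (0.65, 0.65, 5.0)
    sequence_tag: str = "T2WI"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.intensities.shape}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        spacing = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be a positive triple, got {spacing}")
        self.voxel_spacing_mm = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class RoiMask:
    """Binary region-of-interest mask aligned voxel-for-voxel to a volume."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {m.shape}")
        self.mask = m.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DiscretizedVolume:
    """Integer gray-level grid: labels in ``1..n_bins`` inside the mask, 0 outside."""

    labels: np.ndarray
    n_bins: int
    bin_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def _check_geometry(image: VolumeImage, mask: RoiMask) -> None:
    if image.shape != mask.shape:
        raise GeometryMismatchError(
            f"image shape {image.shape} does not match mask shape {mask.shape}"
        )


def zscore_normalize(image: VolumeImage, mask: RoiMask) -> VolumeImage:
    """Standardize in-mask intensities to mean 0 and unit sample SD.

    The sample standard deviation uses the ``n - 1`` denominator.  Voxels
    outside the mask are left untouched.  Applying the transform twice is a
    no-op (up to floating-point round-off).
    """
    _check_geometry(image, mask)
    values = image.intensities[mask.mask]
    if values.size < 2:
        raise DegenerateRegionError("need at least 2 in-mask voxels to standardize")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateRegionError("constant in-mask intensities cannot be z-scored")
    out = image.intensities.copy()
    out[mask.mask] = (values - values.mean()) / sd
    return VolumeImage(out, image.voxel_spacing_mm, image.sequence_tag)


def discretize(image: VolumeImage, mask: RoiMask, n_bins: int = 32) -> DiscretizedVolume:
    """Bin in-mask intensities into ``n_bins`` equal-width gray levels.

    Bins span [in-mask minimum, in-mask maximum]; the maximum maps to the top
    bin.  Discretization is monotone: label order preserves intensity order.
    """
    _check_geometry(image, mask)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = image.intensities[mask.mask]
    if values.size == 0:
        raise DegenerateRegionError("empty mask")
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise DegenerateRegionError("constant in-mask intensities collapse to one bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    lab = np.minimum(np.floor((values - lo) / (hi - lo) * n_bins).astype(int) + 1, n_bins)
    labels = np.zeros(image.shape, dtype=np.int32)
    labels[mask.mask] = lab
    return DiscretizedVolume(labels=labels, n_bins=n_bins, bin_edges=edges)


def discretize_safe(image: VolumeImage, mask: RoiMask, n_bins: int = 32) -> DiscretizedVolume:
    """Like :func:`discretize`, but a constant region maps to a single level.

    Texture matrices are still well defined for a single gray level (all
    co-occurrence mass on one cell, one run level), so the feature bank uses
    this tolerant variant for e.g. detail sub-bands of nearly flat volumes.
    """
    try:
        return discretize(image, mask, n_bins)
    except DegenerateRegionError:
        if mask.n_voxels == 0:
            raise
        warnings.warn("constant region discretized to a single gray level", stacklevel=2)
        labels = np.zeros(image.shape, dtype=np.int32)
        labels[mask.mask] = 1
        v = float(image.intensities[mask.mask][0])
        return DiscretizedVolume(labels=labels, n_bins=1, bin_edges=np.array([v, v]))


def dice(mask_a: RoiMask, mask_b: RoiMask) -> float:
    """DICE overlap 2|A∩B| / (|A|+|B|) between two masks of equal shape."""
    if mask_a.shape != mask_b.shape:
        raise GeometryMismatchError(
            f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}"
        )
    size = mask_a.n_voxels + mask_b.n_voxels
    if size == 0:
        raise DegenerateRegionError("DICE undefined for two empty masks")
    inter = int(np.logical_and(mask_a.mask, mask_b.mask).sum())
    return 2.0 * inter / size


def dice_disagreement(mask_a: RoiMask, mask_b: RoiMask) -> tuple[float, bool]:
    """Return (dice, needs_arbitration): flag raised when 1 - dice > 0.05."""
    d = dice(mask_a, mask_b)
    return d, (1.0 - d) > DICE_DISAGREEMENT_LIMIT


# ---------------------------------------------------------------------------
# NIfTI-1 I/O

def _spacing_from_header(img: nib.Nifti1Image) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def load_volume(path: str, sequence_tag: str = "T2WI") -> VolumeImage:
    """Read a NIfTI-1 volume; voxel spacing is taken from the header zooms."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=float)
    return VolumeImage(data, _spacing_from_header(img), sequence_tag)


def load_mask(path: str, image: VolumeImage | None = None) -> RoiMask:
    """Read a NIfTI-1 binary mask, optionally validating geometry against an image."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    mask = RoiMask(data > 0.5)
    if image is not None:
        if mask.shape != image.shape:
            raise GeometryMismatchError(
                f"mask {path} shape {mask.shape} vs image shape {image.shape}; "
                f"mask spacing {_spacing_from_header(img)} vs image spacing "
                f"{image.voxel_spacing_mm}"
            )
    return mask


def save_volume(path: str, image: VolumeImage) -> None:
    affine = np.diag(list(image.voxel_spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(image.intensities.astype(np.float32), affine), path)


def save_mask(path: str, mask: RoiMask, spacing: tuple[float, float, float]) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), path)
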