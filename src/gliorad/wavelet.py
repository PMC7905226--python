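"""Single-level separable 3D wavelet decomposition into 8 sub-bands.

The default transform is undecimated (stationary / à-trous), so every
sub-band has the grid shape of the input and the original ROI mask can be
reused to pool sub-band voxels — which is what makes wavelet-domain
intensity and texture features well defined.  A decimated orthonormal
reference mode is also exposed; in that mode the sub-band energies sum to
the input energy (Parseval), which serves as a numerical cross-check of the
filter bank.

Sub-bands are keyed ``LLL, LLH, LHL, LHH, HLL, HLH, HHL, HHH`` (L = low
pass, H = high pass, one letter per axis) and indexed 1..8 in that fixed
order; the index is the ``_k`` suffix in wavelet feature names.
"""

from __future__ import annotations

import numpy as np
import pywt

from .preprocess import VolumeImage

__all__ = ["wavelet_decompose", "SUBBAND_ORDER", "subband_index"]

SUBBAND_ORDER = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_PYWT_KEY = {"L": "a", "H": "d"}


def subband_index(name: str) -> int:
    """1-based index of a sub-band in the documented fixed ordering."""
    return SUBBAND_ORDER.index(name) + 1


def _even_pad(data: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Symmetric-pad odd axes to even length (the stationary transform
    requires lengths divisible by 2); the pad is cropped off afterwards."""
    pads = tuple(s % 2 for s in data.shape)
    if any(pads):
        data = np.pad(data, [(0, p) for p in pads], mode="symmetric")
    return data, pads


def wavelet_decompose(
    image: VolumeImage,
    wavelet: str = "coif1",
    undecimated: bool = True,
) -> dict[str, np.ndarray]:
    """Decompose a volume into its 8 low/high sub-bands.

    Parameters
    ----------
    image
        The input volume; each axis must be at least as long as the wavelet
        filter.
    wavelet
        Any PyWavelets basis name (default ``coif1``).
    undecimated
        If True (default), use the stationary transform so sub-bands are
        mask-alignable.  If False, use the decimated transform with
        periodization, the orthonormal reference mode for Parseval checks.

    Returns
    -------
    dict mapping sub-band key (``LLL`` ... ``HHH``) to array.
    """
    data = image.intensities
    w = pywt.Wavelet(wavelet)
    if min(data.shape) < w.dec_len:
        raise ValueError(
            f"grid {data.shape} smaller than the {wavelet} filter length {w.dec_len}"
        )
    if undecimated:
        padded, pads = _even_pad(data)
        coeffs = pywt.swtn(padded, w, level=1)[0]
        crop = tuple(slice(0, s) for s in data.shape)
        out = {}
        for key in SUBBAND_ORDER:
            pywt_key = "".join(_PYWT_KEY[c] for c in key)
            out[key] = np.ascontiguousarray(coeffs[pywt_key][crop])
        return out
    coeffs = pywt.dwtn(data, w, mode="periodization")
    return {
        key: coeffs["".join(_PYWT_KEY[c] for c in key)] for key in SUBBAND_ORDER
    }
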