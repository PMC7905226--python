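import numpy as np
import pytest

from gliorad.crossval import EnetConfig, SvmConfig
from gliorad.preprocess import DiscretizedVolume, RoiMask, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_volume(rng):
    """A 6x6x4 noisy volume with an interior box ROI."""
    data = rng.normal(size=(6, 6, 4))
    mask = np.zeros((6, 6, 4), dtype=bool)
    mask[1:5, 1:5, 1:3] = True
    return VolumeImage(data, (1.0, 1.0, 1.0)), RoiMask(mask)


def random_discretized(rng, shape=(5, 5, 4), ng=4, mask_p=0.7) -> DiscretizedVolume:
    """A random small discretized volume with a random mask."""
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask.flat[0] = True
    labels = np.zeros(shape, dtype=np.int32)
    labels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    return DiscretizedVolume(labels=labels, n_bins=ng)


@pytest.fixture
def fast_enet():
    """Reduced elastic-net grids for quick cross-validation tests."""
    return EnetConfig(alpha_grid=(0.1, 0.5, 1.0), n_lambdas=20, inner_folds=5)


@pytest.fixture
def fast_svm():
    return SvmConfig(
        box_constraint_grid=(0.1, 10.0, 1000.0),
        kernel_scale_grid=(0.46, 10.0, 215.4),
        inner_folds=5,
    )


@pytest.fixture
def tiny_enet():
    """Minimal config for permutation-null replicates."""
    return EnetConfig(alpha_grid=(0.5,), n_lambdas=15, inner_folds=5)


@pytest.fixture
def tiny_svm():
    return SvmConfig(
        box_constraint_grid=(1.0, 100.0), kernel_scale_grid=(1.0, 100.0), inner_folds=5
    )
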