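import numpy as np
import pytest
from hypothesis import settings

from radsurv.features.discretize import discretize
from radsurv.volume_io import ImageVolume, ROIMask

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ellipsoid_case(rng):
    """A 16^3 noisy volume with an ellipsoidal ROI on unit spacing."""
    shape = (16, 16, 16)
    vox = rng.normal(40.0, 20.0, size=shape)
    x, y, z = np.indices(shape)
    mask = ((x - 8) ** 2 / 36 + (y - 8) ** 2 / 25 + (z - 8) ** 2 / 16) <= 1
    return ImageVolume(vox, (1.0, 1.0, 1.0)), ROIMask(mask, (1.0, 1.0, 1.0))


@pytest.fixture
def small_droi(rng):
    """Random 5^3 discretized ROI (8 levels) with a ragged mask."""
    img = rng.integers(0, 40, size=(5, 5, 5)).astype(float)
    mask = rng.random((5, 5, 5)) < 0.8
    mask[2, 2, 2] = True
    return discretize(img, mask, n_bins=8)
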