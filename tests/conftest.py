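import numpy as np
import pytest

from bucketaugment import PhantomConfig, VolumePatch, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def phantom():
    """One small noisy phantom with all three classes present."""
    return make_phantom(PhantomConfig(shape=(24, 24, 24), noise_sigma=0.05,
                                      seed=11))


@pytest.fixture
def phantom_factory():
    def _make(seed, shape=(24, 24, 24), **kwargs):
        kwargs.setdefault("noise_sigma", 0.05)
        return make_phantom(PhantomConfig(shape=shape, seed=seed, **kwargs))

    return _make


@pytest.fixture
def impulse_patch():
    """A single bright voxel at (5, 5, 5) on a zero background."""
    image = np.zeros((12, 12, 12))
    image[5, 5, 5] = 1.0
    label = np.zeros((12, 12, 12), dtype=np.int16)
    label[5, 5, 5] = 1
    return VolumePatch(image, label)
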