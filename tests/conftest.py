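import numpy as np
import pytest

from voteseg import BinaryMask, PhantomConfig, Volume, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """A noiseless 32^3 phantom with 3 teeth: (volume, gt mask)."""
    cfg = PhantomConfig(
        shape=(32, 32, 32), n_teeth=3, crown_semiaxes=(2.5, 2.5, 3.0),
        root_radius=1.5, root_length=4, noise_sd=0.0, seed=7,
    )
    return make_phantom(cfg)


@pytest.fixture
def random_mask(rng):
    def _make(shape=(12, 12, 12), p=0.5, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return BinaryMask(r.random(shape) < p)

    return _make


@pytest.fixture
def random_volume(rng):
    def _make(shape=(8, 9, 10), lo=-1000.0, hi=3000.0):
        return Volume(rng.uniform(lo, hi, size=shape))

    return _make
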