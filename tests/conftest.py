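import numpy as np
import pytest

from snapseg.phantom import MisalignmentSpec, PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A 8x32x32 phantom with its exact geometric label."""
    cfg = PhantomConfig(N=8, H=32, W=32, lumen_radius=4.0, wall_radius=7.0,
                        centerline_amplitude=2.0, seed=7)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def tall_phantom():
    """A 12-slice phantom, for overlapping-window behaviour."""
    cfg = PhantomConfig(N=12, H=32, W=32, lumen_radius=4.0, wall_radius=7.0,
                        centerline_amplitude=2.0, seed=11)
    return generate_phantom(cfg)


@pytest.fixture
def sector_spec():
    return MisalignmentSpec(mode="sector_displace", shift=(3, 0),
                            sector=(0.0, 120.0), affected_slices=(1, 3, 5))


def random_simplex(rng, shape):
    """Random simplex-valued maps with the class axis last."""
    x = rng.gamma(1.0, size=shape + (3,))
    return x / x.sum(axis=-1, keepdims=True)
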