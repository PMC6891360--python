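import numpy as np
import pytest

from dirvessel.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_phantom():
    """One straight-vessel phantom with ground truth and FOV mask."""
    spec = PhantomSpec(
        shape=(128, 128), n_vessels=4, width_range=(2.0, 6.0),
        contrast_range=(0.5, 0.8), curvature=0.0, reflex=False,
        noise_sd=0.01, seed=100,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom():
    """A 64x64 two-vessel phantom for fast end-to-end tests."""
    spec = PhantomSpec(
        shape=(64, 64), n_vessels=2, width_range=(2.0, 4.0),
        contrast_range=(0.5, 0.8), curvature=0.0, reflex=False,
        noise_sd=0.01, seed=7,
    )
    return generate_phantom(spec)
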