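import numpy as np
import pytest

from fundus_xai import (
    InputSpec,
    make_intensity_linear_model,
    make_region_fraction_model,
    make_tiny_cnn,
)


@pytest.fixture(scope="session")
def small_spec():
    """8x8 RGB spec: large enough for two stride-2 stages, cheap to brute-force."""
    return InputSpec(height=8, width=8, channels=3, num_classes=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_image(small_spec):
    return np.random.default_rng(7).uniform(0.05, 0.95, small_spec.shape)


@pytest.fixture(scope="session")
def linear_model(small_spec):
    return make_intensity_linear_model(small_spec, seed=11)


@pytest.fixture(scope="session")
def tiny_cnn(small_spec):
    return make_tiny_cnn(small_spec, seed=3)


@pytest.fixture(scope="session")
def region_10x10():
    """10x10 spec with a planted 20-pixel region (20% of the image)."""
    spec = InputSpec(height=10, width=10, channels=3, num_classes=5)
    region = np.zeros((10, 10), dtype=bool)
    region[:2, :] = True
    return make_region_fraction_model(region, spec), region, spec


def finite_difference_gradient(handle, image, target, h=1e-4):
    """Central finite differences of the target score over every intensity."""
    g = np.zeros_like(image)
    it = np.nditer(image, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = image.copy()
        xp[idx] += h
        xm = image.copy()
        xm[idx] -= h
        g[idx] = (handle.score(xp, target) - handle.score(xm, target)) / (2 * h)
        it.iternext()
    return g
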