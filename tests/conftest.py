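import numpy as np
import pytest

from histosift import synthetic
from histosift.sift import SiftParams, build_scale_space, compute_dog, extract_features


@pytest.fixture(scope="session")
def texture():
    """One mixed-size synthetic texture tile (300x300, seeded)."""
    return synthetic.render_image(synthetic.default_class_specs()[4], 7)


@pytest.fixture(scope="session")
def texture_features(texture):
    return extract_features(texture)


@pytest.fixture(scope="session")
def texture_scale_space(texture):
    ss = build_scale_space(texture, SiftParams())
    return ss, compute_dog(ss)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_l1_histograms(n: int, bins: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    h = rng.random((n, bins))
    return h / h.sum(axis=1, keepdims=True)
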