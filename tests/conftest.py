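import numpy as np
import pytest

from rgcsc.image_features import ContrastImage
from rgcsc.receptive_field import GaussianRF
from rgcsc.synthetic import SyntheticImageSetSpec, generate_images


@pytest.fixture(scope="session")
def small_images():
    """20 natural-like images on a 64-px grid (session-cached)."""
    spec = SyntheticImageSetSpec(n_images=20, size_px=64, seed=123)
    return generate_images(spec)


@pytest.fixture(scope="session")
def circular_rf():
    """Circular Gaussian RF centered on the 64-px grid (sigma = 6 px)."""
    return GaussianRF(mu=[31.5, 31.5], sigma=np.eye(2) * 36.0, pixel_pitch=7.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def uniform_image():
    def make(value, size=64, pitch=7.5):
        return ContrastImage(values=np.full((size, size), float(value)),
                             pixel_pitch=pitch)
    return make
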