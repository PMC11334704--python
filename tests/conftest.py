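import numpy as np
import pytest

from octavd.image import EnFaceImage
from octavd.synthetic import ImageParams, generate_vessel_image


@pytest.fixture(scope="session")
def noiseless_params() -> ImageParams:
    return ImageParams(additive_sd=0.0, speckle_sd=0.0, falloff=0.0)


@pytest.fixture(scope="session")
def noiseless_image(noiseless_params):
    """Two-level synthetic angiogram with exact ground truth."""
    return generate_vessel_image(noiseless_params, seed=3)


@pytest.fixture(scope="session")
def default_image():
    """Synthetic angiogram at the default noise/falloff settings."""
    return generate_vessel_image(ImageParams(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_small_image(rng) -> EnFaceImage:
    return EnFaceImage(rng.integers(0, 256, (16, 16)).astype(np.uint8))
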