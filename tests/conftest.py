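import numpy as np
import pytest

from rodtrack.config import OpticsConfig


@pytest.fixture
def optics128() -> OpticsConfig:
    return OpticsConfig(image_height=128, image_width=128, seed=0)


@pytest.fixture
def optics_clean() -> OpticsConfig:
    """Noise-free, shading-free optics for geometry tests."""
    return OpticsConfig(image_height=128, image_width=128, noise_sigma=0.0,
                        illum_gradient_amp=0.0, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
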