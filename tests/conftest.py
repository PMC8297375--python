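import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xraykit import GrayImage, PhantomSpec, make_phantom

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng) -> GrayImage:
    """Unstructured 8-bit noise image, the adversarial case for every codec."""
    return GrayImage(rng.integers(0, 256, size=(32, 32)))


@pytest.fixture(scope="session")
def chest_phantom() -> GrayImage:
    """The standard noisy chest-like evaluation image (fixed seed)."""
    return make_phantom(PhantomSpec("chest_like", (256, 256), seed=42, noise_sigma=2.0))


@pytest.fixture(scope="session")
def blocky_phantom() -> GrayImage:
    return make_phantom(PhantomSpec("blocky", (64, 64), seed=7))


def make_image(array, bit_depth: int = 8) -> GrayImage:
    return GrayImage(np.asarray(array, dtype=np.int64), bit_depth)
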