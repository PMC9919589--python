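import numpy as np
import pytest

from seepvision.imaging import ImageRGB
from seepvision.synthetic import make_fixture_set


def random_image(rng: np.random.Generator, h: int = 32, w: int = 32) -> ImageRGB:
    """Uniform-random 8-bit test image."""
    return ImageRGB(
        rng.integers(0, 256, size=(h, w, 3)).astype(np.float64),
        source_id=f"rand_{rng.integers(1 << 30)}",
    )


@pytest.fixture(scope="session")
def fixture_set_40():
    """40 synthetic clean/degraded pairs at 64x64, fixed seed, in memory."""
    return make_fixture_set(40, seed=20240, out_dir=None, conditions=5, size=(64, 64))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
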