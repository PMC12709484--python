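import numpy as np
import pytest

from tissuefractal.image_io import GrayImage
from tissuefractal.synthetic import CarpetSpec, CascadeSpec, make_carpet, make_cascade


@pytest.fixture(scope="session")
def sierpinski():
    """Level-4 Sierpinski carpet (81x81), analytic dimension ln8/ln3."""
    return make_carpet(CarpetSpec(base=3, retained=8, levels=4))


@pytest.fixture(scope="session")
def cascade_04():
    """Level-6 binomial cascade with weights (0.4, 0.3, 0.2, 0.1)."""
    return make_cascade(CascadeSpec(weights=(0.4, 0.3, 0.2, 0.1), levels=6))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def noisy_image(rng):
    """A 120x120 random grayscale image."""
    return GrayImage(rng.integers(0, 256, size=(120, 120)))
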