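import numpy as np
import pytest

from paradetect.geometry import Parabola, rasterize
from paradetect.umda import index_pixels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def narrow_parabola():
    """A crisp sideways parabola centred in a 128x128 frame."""
    A = 0.05
    y_v, x_v = 64.0, 20.0
    return Parabola(A, -2 * A * y_v, A * y_v * y_v + x_v)


@pytest.fixture
def narrow_parabola_image(narrow_parabola):
    grid = rasterize(narrow_parabola, 128, 128)
    return index_pixels(grid)


def random_parabola(rng, a_range=(1e-3, 5.0)):
    """Random nondegenerate coefficients for property tests."""
    a = rng.uniform(*a_range) * rng.choice([-1.0, 1.0])
    b = rng.uniform(-10, 10)
    c = rng.uniform(-100, 100)
    return Parabola(a, b, c)
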