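import numpy as np
import pytest

from conemosaic import ConeField, Window


@pytest.fixture
def big_window() -> Window:
    return Window(100.0, 100.0)


def uniform_field(n: int, window: Window, seed: int,
                  label: str = "single") -> ConeField:
    """Unconstrained (binomial/Poisson-like) random field of one class."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0, 0], [window.width, window.height], size=(n, 2))
    return ConeField(pts, np.asarray([label] * n, dtype=object), window)


@pytest.fixture
def make_uniform_field():
    return uniform_field
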