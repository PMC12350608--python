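import numpy as np
import pytest

from otoshape import Contour, ShapeParams, generate_contour


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def circle_contour():
    t = np.linspace(0.0, 2.0 * np.pi, 1000, endpoint=False)
    return Contour(np.column_stack([np.cos(t), np.sin(t)]))


@pytest.fixture
def ellipse_contour():
    t = np.linspace(0.0, 2.0 * np.pi, 2000, endpoint=False)
    return Contour(np.column_stack([2.0 * np.cos(t), np.sin(t)]))


@pytest.fixture
def square_contour():
    return Contour(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def otolith_contour():
    """A deterministic default synthetic otolith outline."""
    return generate_contour(ShapeParams(irregularity_sd=0.0))
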