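import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from vcogm.synthetic import ShapeSpec, make_shape_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def shape_image():
    """One deterministic 32x32 square-on-dark shape image with contour mask."""
    return make_shape_image(ShapeSpec(family="square"), seed=7)


@pytest.fixture
def small_shape_image():
    """16x16 shapes fixture for the more expensive brute-force recomputations."""
    return make_shape_image(ShapeSpec(family="ellipse", height=16, width=16), seed=3)


def random_gray(rng, H, W):
    """A random image strictly inside [-1, 1]."""
    return rng.uniform(-0.95, 0.95, size=(H, W))
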