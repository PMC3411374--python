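import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def plus_skeleton():
    """Two crossing 1-px lines: 4 tips, one crossing."""
    img = np.zeros((11, 11), dtype=bool)
    img[5, :] = True
    img[:, 5] = True
    return img


@pytest.fixture
def t_skeleton():
    """A T junction whose candidate pixels form a 2-pixel cluster."""
    img = np.zeros((6, 8), dtype=bool)
    img[0, 0:7] = True
    img[0:5, 3] = True
    return img


@pytest.fixture
def line_skeleton():
    img = np.zeros((5, 12), dtype=bool)
    img[2, 1:11] = True  # straight 1-px line of length 10
    return img
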