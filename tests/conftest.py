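import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

from bregrestore import PSFKernel, gaussian_kernel, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_kernel():
    return PSFKernel(np.array([[1.0]]))


@pytest.fixture
def blur5():
    return gaussian_kernel(5, 1.5)


@pytest.fixture
def piecewise64():
    return make_phantom("piecewise", 64, seed=0)


@pytest.fixture
def textured64():
    return make_phantom("textured", 64, seed=0)


@pytest.fixture
def smooth64():
    return make_phantom("smooth", 64, seed=0)
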