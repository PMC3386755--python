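import numpy as np
import pytest

from nanocyp import Nanotube, ProteinPrism, make_orientation_set


@pytest.fixture(scope="session")
def protein():
    return ProteinPrism()  # midpoint crystallographic dimensions


@pytest.fixture(scope="session")
def tube():
    return Nanotube(diameter=10.0, length=1000.0)


@pytest.fixture(scope="session")
def orientations(protein, tube):
    return make_orientation_set(protein, tube)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
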