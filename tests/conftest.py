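import numpy as np
import pytest

from posesieve.fixtures import make_born_system, make_cyclic_ligand, make_toy_receptor


@pytest.fixture(scope="session")
def receptor():
    return make_toy_receptor(seed=0)


@pytest.fixture(scope="session")
def ligand():
    return make_cyclic_ligand(seed=0)


@pytest.fixture(scope="session")
def born_ion():
    return make_born_system(charges=(1.0,), radius=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
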