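import numpy as np
import pytest

import cgdock as cg
from cgdock.fixtures import make_ideal_helix, make_random_coil


@pytest.fixture(scope="session")
def lattice():
    return cg.default_lattice()


@pytest.fixture(scope="session")
def ff():
    return cg.default_force_field()


@pytest.fixture(scope="session")
def helix_chain(lattice):
    xyz, seq = make_ideal_helix(30, seed=1)
    trace, _ = cg.project_chain(xyz, lattice)
    return cg.rebuild_pseudoatoms(trace, seq, lattice)


@pytest.fixture(scope="session")
def coil_chain(lattice):
    xyz, seq = make_random_coil(30, seed=2)
    trace, _ = cg.project_chain(xyz, lattice)
    return cg.rebuild_pseudoatoms(trace, seq, lattice)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
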