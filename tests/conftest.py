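import numpy as np
import pytest

from cation_allostery import fixtures, structure_io as sio


@pytest.fixture(scope="session")
def toy():
    return fixtures.gen_toy_receptor()


@pytest.fixture(scope="session")
def toy_structure(toy):
    return sio.read_structure(toy.pdb_text)


@pytest.fixture(scope="session")
def toy_network(toy_structure):
    return sio.build_network(toy_structure)


@pytest.fixture(scope="session")
def atom_index(toy_network):
    return {(a.resnum, a.name): i for i, a in enumerate(toy_network.atoms)}


@pytest.fixture(scope="session")
def bridge_atoms(toy, atom_index):
    (r1, o1), (r2, o2) = toy.bridge_atoms
    return atom_index[(r1, o1)], atom_index[(r2, o2)]


def random_framework(seed, n=None):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(2, 13))
    return fixtures.gen_framework(
        fixtures.FrameworkSpec(template="random", n_bodies=n, seed=seed)
    )
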