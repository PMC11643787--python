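import numpy as np
import pytest
from hypothesis import settings

import loxqsar as lq

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from loxqsar.molgraph import Atom, Bond, MolecularGraph


@pytest.fixture(scope="session")
def props():
    return lq.load_default_properties()


@pytest.fixture
def methane():
    return MolecularGraph(atoms=[Atom("C")], bonds=[])


@pytest.fixture
def water():
    return MolecularGraph(atoms=[Atom("O")], bonds=[])


@pytest.fixture
def benzene():
    return lq.read_structures("c1ccccc1", "smiles")[0]


@pytest.fixture
def toluene():
    return lq.read_structures("Cc1ccccc1", "smiles")[0]


@pytest.fixture
def ethanol():
    return lq.read_structures("CCO", "smiles")[0]


@pytest.fixture
def biphenyl():
    return lq.read_structures("c1ccc(-c2ccccc2)cc1", "smiles")[0]


@pytest.fixture(scope="session")
def fixture_graphs():
    """Small heterogeneous molecules (<= 12 heavy atoms) for oracle checks."""
    smis = [
        "CCO", "c1ccccc1", "Cc1ccccc1", "C1CCCCC1", "CC(C)CO",
        "c1ccncc1", "CSC", "OC(=O)CCl", "c1ccc2ccccc2c1", "C1CC1CBr",
    ]
    return lq.read_structures("\n".join(smis), "smiles")


def permute_graph(graph: MolecularGraph, rng: np.random.Generator) -> MolecularGraph:
    """Relabel atoms with a random permutation (test utility)."""
    perm = rng.permutation(graph.n_atoms)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(graph.n_atoms)
    atoms = [graph.atoms[j] for j in perm]
    bonds = [Bond(int(inv[b.i]), int(inv[b.j]), b.order) for b in graph.bonds]
    return MolecularGraph(atoms=atoms, bonds=bonds, name=graph.name)


@pytest.fixture(scope="session")
def s1_like():
    return lq.make_s1_like(11)


@pytest.fixture(scope="session")
def trs1(s1_like):
    return lq.ranked_split(s1_like).train
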