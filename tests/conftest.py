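"""Shared fixtures: synthetic complexes, mappings, and a toy model."""

import numpy as np
import pytest

from duores.demo import ToyComplexModel
from duores.mapping import Mapping, select_atomistic
from duores.structures import make_toy_complex


@pytest.fixture(scope="session")
def toy():
    """A 14-residue synthetic complex with a multi-atom ligand."""
    return make_toy_complex(14, seed=3)


@pytest.fixture(scope="session")
def mapping4(toy):
    """Mapping with the four residues closest to the ligand atomistic."""
    return select_atomistic(toy, 4)


@pytest.fixture(scope="session")
def full_cg(toy):
    """Fully coarse-grained mapping (every residue an ENM bead)."""
    return Mapping(atomistic=[], cg=[r.index for r in toy.residues])


@pytest.fixture(scope="session")
def model(toy, mapping4):
    """Toy complex force field built on the 14-residue fixture."""
    return ToyComplexModel.build(toy, mapping4)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
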