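import numpy as np
import pytest

from pathcolor.chem_io import Atom, MoleculeGraph
from pathcolor.synthdata import SynthConfig, generate_study

WATER_MOLFILE = """water
  pathcolor

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
M  END
"""


@pytest.fixture
def water_molfile():
    return WATER_MOLFILE


@pytest.fixture
def water():
    return MoleculeGraph(
        "water",
        [Atom("O"), Atom("H"), Atom("H")],
        [(0, 1, 1), (0, 2, 1)],
    )


@pytest.fixture
def methane():
    return MoleculeGraph(
        "methane",
        [Atom("C"), Atom("H"), Atom("H"), Atom("H"), Atom("H")],
        [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1)],
    )


@pytest.fixture
def ethanol():
    # C-C-O plus 6 hydrogens
    atoms = [Atom("C"), Atom("C"), Atom("O")] + [Atom("H")] * 6
    bonds = [(0, 1, 1), (1, 2, 1)]
    bonds += [(0, 3, 1), (0, 4, 1), (0, 5, 1), (1, 6, 1), (1, 7, 1), (2, 8, 1)]
    return MoleculeGraph("ethanol", atoms, bonds)


@pytest.fixture
def benzene():
    atoms = [Atom("C")] * 6
    bonds = [(i, (i + 1) % 6, 4) for i in range(6)]
    return MoleculeGraph("benzene", atoms, bonds)


@pytest.fixture
def glucose():
    # C6H12O6 as a schematic heavy-atom skeleton: ring of 5 C + 1 O,
    # exocyclic CH2OH carbon and hydroxyl oxygens; 12 heavy atoms total.
    atoms = [Atom("C")] * 6 + [Atom("O")] * 6 + [Atom("H")] * 12
    bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 6, 1), (6, 0, 1)]
    bonds += [(0, 5, 1)]  # exocyclic carbon
    bonds += [(1, 7, 1), (2, 8, 1), (3, 9, 1), (4, 10, 1), (5, 11, 1)]
    bonds += [(12 + i, i % 6, 1) for i in range(12)]
    return MoleculeGraph("glucose", atoms, bonds)


@pytest.fixture(scope="session")
def small_study():
    """Small deterministic synthetic benchmark shared across tests."""
    return generate_study(
        SynthConfig(n_compounds=40, n_pathways=10, hierarchy_depth=3, seed=7)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
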