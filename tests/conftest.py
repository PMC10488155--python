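import numpy as np
import pytest

from ptmpack.energy import PackingSystem, load_param_table
from ptmpack.fixtures import FixtureSpec, make_packing_puzzle, make_toy_structure
from ptmpack.topology import registry


@pytest.fixture(scope="session")
def reg():
    return registry()


@pytest.fixture(scope="session")
def param_table():
    return load_param_table()


@pytest.fixture(scope="session")
def ser_helix():
    """Clash-free 5-residue poly-serine helix at chi1 = -60 everywhere."""
    return make_toy_structure(
        FixtureSpec(["SER"] * 5, "helix", chi_assignment=[[-60.0]] * 5))


@pytest.fixture(scope="session")
def puzzle():
    """3-residue x 5-rotamer enumerable packing puzzle."""
    return make_packing_puzzle(3, [5, 5, 5], seed=1)


@pytest.fixture(scope="session")
def puzzle_system(puzzle):
    return PackingSystem(puzzle.structure, puzzle.movable)


ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.060  1.00 10.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00 10.00           C
END
"""


@pytest.fixture()
def ala_pdb_text():
    return ALA_PDB
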