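import numpy as np
import pytest

import glowdock as gd


@pytest.fixture(scope="session")
def toy_complex():
    """Deterministic toy receptor-ligand complex with native pose and restraints."""
    return gd.make_toy_complex(seed=7)


@pytest.fixture(scope="session")
def toy_antibody():
    return gd.make_toy_antibody()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_pdb_text():
    """Hand-written 3-residue fragment with an altloc pair, a water and a bead."""
    return (
        "MODEL        1\n"
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  CA AGLY A   2       3.000   1.000   0.000  1.00  0.00           C\n"
        "ATOM      4  CA BGLY A   2       3.200   1.100   0.000  1.00  0.00           C\n"
        "ATOM      5  CA  SER B   5       5.000   2.000   1.000  1.00  0.00\n"
        "HETATM    6  O   HOH W   1       9.000   9.000   9.000  1.00  0.00           O\n"
        "HETATM    7  BJ  MMB M   1       2.000   2.000  15.000  1.00  0.00\n"
        "ENDMDL\n"
        "MODEL        2\n"
        "ATOM      8  CA  ALA A   9      20.000  20.000  20.000  1.00  0.00           C\n"
        "ENDMDL\n"
        "END\n"
    )
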