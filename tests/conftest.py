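import numpy as np
import pytest

from conflock.energy import load_reference_tables
from conflock.synthetic import synthetic_interface_structure

TWO_CHAIN_PDB = "HEADER" + " " * 56 + "TOY1\n" + """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
TER
ATOM      3  N   ALA B   1       0.000   4.000   0.000  1.00  0.00           N
ATOM      4  CA  ALA B   1       1.450   4.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture(scope="session")
def reference_tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def all_rows(reference_tables):
    t1, t2 = reference_tables
    return t1 + t2


@pytest.fixture(scope="session")
def interface_structure():
    return synthetic_interface_structure()


def constant_trace(pair, component, value, n=100, dt=1.0):
    from conflock.energy import EnergyTrace

    t = np.arange(n) * dt
    return EnergyTrace(pair=pair, component=component,
                       times=t, values=np.full(n, float(value)))
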