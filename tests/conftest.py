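import numpy as np
import pytest

import redoxmc as rx

MINIMAL_CYS_PDB = """\
ATOM      1  N   CYS A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  CYS A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   CYS A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   CYS A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  CYS A   1       1.993  -0.773  -1.210  1.00  0.00           C
ATOM      6  SG  CYS A   1       3.789  -0.876  -1.279  1.00  0.00           S
END
"""

SF4_PDB = """\
HETATM    1 FE1  SF4 A 500      -1.150  -1.150  -1.150  1.00  0.00          FE
HETATM    2 FE2  SF4 A 500       1.150   1.150  -1.150  1.00  0.00          FE
HETATM    3 FE3  SF4 A 500       1.150  -1.150   1.150  1.00  0.00          FE
HETATM    4 FE4  SF4 A 500      -1.150   1.150   1.150  1.00  0.00          FE
HETATM    5  S1  SF4 A 500       1.150  -1.150  -1.150  1.00  0.00           S
HETATM    6  S2  SF4 A 500      -1.150   1.150  -1.150  1.00  0.00           S
HETATM    7  S3  SF4 A 500      -1.150  -1.150   1.150  1.00  0.00           S
HETATM    8  S4  SF4 A 500       1.150   1.150   1.150  1.00  0.00           S
END
"""

WATER_PDB = MINIMAL_CYS_PDB.replace(
    "END\n",
    "HETATM    7  O   HOH A 101       8.000   8.000   8.000  1.00  0.00           O\nEND\n",
)


@pytest.fixture(scope="session")
def config():
    return rx.default_charge_config()


@pytest.fixture(scope="session")
def fixtures():
    return rx.load_published_fixtures()


@pytest.fixture(scope="session")
def cubane_model(config):
    model, pdb, cfg = rx.make_toy_cluster(rx.ToySystemSpec(n_fe=4, seed=11))
    return model


def random_titration_system(rng, max_conformers=10):
    """Random small redox system: 2-4 coupled sites within a conformer budget."""
    n_sites = int(rng.integers(2, 5))
    n_sites = min(n_sites, max_conformers // 2)
    ems = rng.uniform(-450, -100, size=n_sites)
    W = np.abs(rng.normal(0.0, 1.2, size=(n_sites, n_sites)))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    shifts = rng.normal(0.0, 1.5, size=n_sites)
    return rx.make_titration_system(list(ems), W=W, protein_shift=list(shifts))
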