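import numpy as np
import pytest

from dynatile.anm import AnmParams, compute_cross_correlation
from dynatile.fixtures import FixtureSpec, make_toy_domain

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  CYS A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      4  SG  CYS A   3       7.600   2.800   0.000  1.00  0.00           S
END
"""

HETATM_ONLY_PDB = """\
HETATM    1 FE1  SF4 A 101       1.000   2.000   3.000  1.00  0.00          FE
HETATM    2 FE2  SF4 A 101       3.000   2.000   1.000  1.00  0.00          FE
HETATM    3 CA    CA A 102       9.000   9.000   9.000  1.00  0.00          CA
END
"""


@pytest.fixture(scope="session")
def helix_structure():
    structure, _ = make_toy_domain(FixtureSpec(domain_length=30, fold="helix", seed=3))
    return structure

@pytest.fixture(scope="session")
def helix_corr(helix_structure):
    return compute_cross_correlation(helix_structure, AnmParams())


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def hetatm_only_pdb(tmp_path):
    path = tmp_path / "hetatm.pdb"
    path.write_text(HETATM_ONLY_PDB)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(0)
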