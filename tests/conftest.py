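import pytest

from lipscan.fixtures import (
    FixtureSpec,
    leucine_bundle_spec,
    make_structure,
    polar_bundle_spec,
)
from lipscan.lip import find_lips

# Minimal hand-built dipeptide: Ala (5 heavy atoms) + Gly (4 heavy atoms).
ALA_GLY_PDB = """\
ATOM      1  N   ALA A   1      -0.525   1.362   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.520   0.000   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.197   1.010   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1      -0.507  -0.785  -1.207  1.00  0.00           C
ATOM      6  N   GLY A   2       2.088  -1.200   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.523  -1.362   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       4.247  -0.069   0.352  1.00  0.00           C
ATOM      9  O   GLY A   2       5.408  -0.088   0.748  1.00  0.00           O
ATOM     10  H   GLY A   2       1.500  -2.000   0.000  1.00  0.00           H
TER      11      GLY A   2
END
"""


@pytest.fixture(scope="session")
def ala_gly_pdb() -> str:
    return ALA_GLY_PDB


@pytest.fixture(scope="session")
def helix20():
    """20-residue mixed-sequence ideal helix."""
    spec = FixtureSpec(sequences=["ASLKEDAQRTVLSWNGFYTM"], geometry="ideal-helix")
    structure, text = make_structure(spec)
    return structure, text


@pytest.fixture(scope="session")
def polar_bundle():
    """Loose serine/asparagine-faced two-helix bundle (positive control)."""
    structure, text = make_structure(polar_bundle_spec())
    return structure, text


@pytest.fixture(scope="session")
def leucine_bundle():
    """Tight all-leucine two-helix bundle (negative control)."""
    structure, text = make_structure(leucine_bundle_spec())
    return structure, text


@pytest.fixture(scope="session")
def polar_analysis(polar_bundle):
    structure, _text = polar_bundle
    return find_lips(structure, mode="intra")


@pytest.fixture(scope="session")
def leucine_analysis(leucine_bundle):
    structure, _text = leucine_bundle
    return find_lips(structure, mode="intra")
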