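import numpy as np
import pytest

from homodel.restraints import build_hddrs
from homodel.synthetic_data import ToySpec, build_native, generate_pair


@pytest.fixture(scope="session")
def helix_pair():
    """Single-template toy: 16-residue helix, ~1.5 A divergence."""
    return generate_pair(ToySpec(length=16, fold="helix", divergence=1.5, seed=7))


@pytest.fixture(scope="session")
def multi_pair():
    """Three templates of increasing divergence on an 18-residue mixed fold."""
    return generate_pair(
        ToySpec(length=18, fold="mixed", divergence=1.5, n_templates=3, seed=21)
    )


@pytest.fixture(scope="session")
def helix_restraints(helix_pair):
    native, templates, aln = helix_pair
    return build_hddrs(aln, templates, native)


@pytest.fixture(scope="session")
def tiny_native():
    return build_native(10, "helix", "LEKFDILETK", "tiny")


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.985   2.831   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.498   2.706   0.000  1.00  0.00           C
ATOM      8  O   GLY A   2       6.055   1.610   0.000  1.00  0.00           O
TER
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    return p
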