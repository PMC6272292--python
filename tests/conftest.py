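import numpy as np
import pytest

from vinarf.simdata import ComplexGenSpec, gen_complex


LIGAND_PDBQT = """\
REMARK  3 active torsions:
ATOM      1  C   LIG A   1       0.000   0.000   0.000  1.00  0.00    +0.000 C
ATOM      2  C   LIG A   1       1.500   0.000   0.000  1.00  0.00    +0.000 C
ATOM      3  O   LIG A   1       2.200   1.100   0.000  1.00  0.00    +0.000 OA
ATOM      4  N   LIG A   1      -1.400   0.500   0.300  1.00  0.00    +0.000 N
ATOM      5  H   LIG A   1      -1.900   1.200   0.800  1.00  0.00    +0.000 HD
BRANCH   1   2
BRANCH   2   3
BRANCH   1   4
"""

PROTEIN_PDB = """\
ATOM      1  N   ALA A   1       4.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       5.200   0.800   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       6.500   0.000   0.200  1.00  0.00           C
ATOM      4  O   ALA A   1       6.600  -1.200   0.100  1.00  0.00           O
ATOM      5  CB  ALA A   1       5.300   2.100   0.800  1.00  0.00           C
ATOM      6  H   ALA A   1       3.900  -0.900  -0.400  1.00  0.00           H
HETATM    7  O   HOH A  90       8.000   8.000   8.000  1.00  0.00           O
HETATM    8 ZN   ZN  A  91      -8.000  -8.000  -8.000  1.00  0.00          ZN
"""


@pytest.fixture
def ligand_pdbqt() -> str:
    return LIGAND_PDBQT


@pytest.fixture
def protein_pdb() -> str:
    return PROTEIN_PDB


@pytest.fixture
def small_complex():
    """A deterministic 30+10-atom synthetic complex."""
    return gen_complex(ComplexGenSpec(n_protein_atoms=30, n_ligand_atoms=10), seed=42)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
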