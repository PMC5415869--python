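import numpy as np
import pytest

from skinmorph.io_pdb import random_ball_set
from skinmorph.wp_algebra import BallSet


TWO_ATOM_PDB = """\
ATOM      1  C   LIG A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  O   LIG A   1       1.500   0.000   0.000  1.00  0.00           O
END
"""

THREE_ATOM_PDB = """\
ATOM      1  C   LIG A   1       0.300   0.200   0.000  1.00  0.00           C
ATOM      2  N   LIG A   1       1.600   0.300   0.400  1.00  0.00           N
ATOM      3  O   LIG A   1       0.500   1.500  -0.300  1.00  0.00           O
END
"""


@pytest.fixture
def two_atom_pdb(tmp_path):
    p = tmp_path / "two.pdb"
    p.write_text(TWO_ATOM_PDB)
    return p


@pytest.fixture
def three_atom_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p


@pytest.fixture
def symmetric_pair():
    """Two equal balls straddling the plane x = 0."""
    return BallSet([[-1.0, 0, 0], [1.0, 0, 0]], [2.0, 2.0])


@pytest.fixture
def unit_tetrahedron():
    T = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    return BallSet(T, np.ones(4))


def random_morph_pair(seed: int, m: int, n: int):
    src = random_ball_set(m, seed)
    tgt = random_ball_set(n, seed + 100, offset=np.array([0.5, 0.3, -0.2]))
    return src, tgt
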