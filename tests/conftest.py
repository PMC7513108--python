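import math

import numpy as np
import pytest

from confent.synthetic import build_chain
from confent.thermo import load_reference_energy_table

# Hand-written 3-residue PDB (Ala-Gly-Ser backbone) used for parser tests.
PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.978   2.839   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.494   2.720   0.000  1.00  0.00           C
ATOM      8  O   GLY A   2       6.030   1.610   0.000  1.00  0.00           O
ATOM      9  N   SER A   3       6.179   3.856   0.000  1.00  0.00           N
ATOM     10  CA  SER A   3       7.633   3.855   0.000  1.00  0.00           C
ATOM     11  C   SER A   3       8.160   5.280   0.000  1.00  0.00           C
ATOM     12  O   SER A   3       7.400   6.250   0.000  1.00  0.00           O
ATOM     13  CB  SER A   3       8.180   3.100   1.210  1.00  0.00           C
ATOM     14  OG  SER A   3       7.700   1.770   1.260  1.00  0.00           O
END
"""


@pytest.fixture
def pdb_3res(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(PDB_3RES)
    return p


@pytest.fixture
def table1():
    return load_reference_energy_table()


HELIX_PHI = math.radians(-57.0)
HELIX_PSI = math.radians(-47.0)


def helix_targets(n):
    return {i: {"phi": HELIX_PHI, "psi": HELIX_PSI} for i in range(1, n + 1)}


@pytest.fixture
def helix10():
    return build_chain("A" * 10, helix_targets(10), name="helix10")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_rigid_motion(rng):
    """A uniformly random proper rotation matrix and a translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-20, 20, size=3)
    return R, t
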