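"""Shared fixtures and the external secondary-structure reference oracle."""

import os
import tempfile
import warnings

import numpy as np
import pytest

from chaincompare.fixtures import (
    make_beta_hairpin,
    make_hinge_pair,
    make_ideal_helix,
    write_fixture,
)

# a small single-chain PDB with resolution header, SEQRES and B-factors,
# used by the parsing tests (hand-written, standards-conformant records)
MINI_PDB = """\
HEADER    DE NOVO PROTEIN                         01-JAN-20   XXXX
REMARK   2 RESOLUTION.    1.50 ANGSTROMS.
SEQRES   1 A    5  ALA GLY ALA ALA GLY
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 11.00           C
ATOM      3  C   ALA A   1       2.004   1.420   0.000  1.00 12.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 13.00           O
ATOM      5  N   GLY A   2       3.320   1.540   0.000  1.00 14.00           N
ATOM      6  CA  GLY A   2       3.950   2.850   0.000  1.00 15.00           C
ATOM      7  C   GLY A   2       5.460   2.750   0.000  1.00 16.00           C
ATOM      8  O   GLY A   2       6.030   1.660   0.000  1.00 17.00           O
ATOM      9  N   ALA A   3       6.120   3.900   0.000  1.00 18.00           N
ATOM     10  CA  ALA A   3       7.570   3.970   0.000  1.00 19.00           C
ATOM     11  C   ALA A   3       8.110   5.390   0.000  1.00 20.00           C
ATOM     12  O   ALA A   3       7.360   6.360   0.000  1.00 21.00           O
ATOM     13  N   ALA A   4       9.430   5.510   0.000  1.00 22.00           N
ATOM     14  CA  ALA A   4      10.060   6.820   0.000  1.00 23.00           C
ATOM     15  C   ALA A   4      11.570   6.720   0.000  1.00 24.00           C
ATOM     16  O   ALA A   4      12.140   5.630   0.000  1.00 25.00           O
ATOM     17  N   GLY A   5      12.230   7.870   0.000  1.00 26.00           N
ATOM     18  CA  GLY A   5      13.680   7.940   0.000  1.00 27.00           C
ATOM     19  C   GLY A   5      14.220   9.360   0.000  1.00 28.00           C
ATOM     20  O   GLY A   5      13.470  10.330   0.000  1.00 29.00           O
END
"""


@pytest.fixture(scope="session")
def helix15():
    return make_ideal_helix(15)


@pytest.fixture(scope="session")
def hairpin():
    return make_beta_hairpin(6)


@pytest.fixture(scope="session")
def hinge_pair():
    return make_hinge_pair(30, 15, 20.0)


@pytest.fixture(scope="session")
def arg_helix():
    names = ["ALA"] * 12
    names[6] = "ARG"
    return make_ideal_helix(12, residue_names=names)


@pytest.fixture
def mini_pdb_path(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return str(p)


def reference_dssp_three_state(chain) -> str:
    """Independent oracle: an externally developed hydrogen-bond secondary
    structure implementation (MDAnalysis' port of pydssp), run on a PDB file
    written from the chain.  Returns a per-residue H/E/O string."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
        from MDAnalysis.analysis.dssp import DSSP

        with tempfile.TemporaryDirectory() as td:
            path = os.path.join(td, "chain.pdb")
            write_fixture(chain, path)
            states = DSSP(mda.Universe(path), guess_hydrogens=True).run().results.dssp[0]
    return "".join("O" if s == "-" else s for s in states)


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()
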