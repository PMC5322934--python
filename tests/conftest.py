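import numpy as np
import pytest

from mdcckit.trajio import Atom, Residue, Topology, Trajectory

GLYCINE_PDB = """\
ATOM      1  N   GLY A   1      -0.500   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.958   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       1.500   1.400   0.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY B   1       0.000   8.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY B   2       3.800   8.000   0.000  1.00  0.00           C
END
"""

DUPLICATE_ATOM_PDB = """\
ATOM      1  N   GLY A   1      -0.500   0.000   0.000  1.00  0.00           N
ATOM      2  N   GLY A   1       0.958   0.000   0.000  1.00  0.00           N
END
"""


@pytest.fixture
def glycine_pdb(tmp_path):
    p = tmp_path / "gly.pdb"
    p.write_text(GLYCINE_PDB)
    return p


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture
def duplicate_atom_pdb(tmp_path):
    p = tmp_path / "dup.pdb"
    p.write_text(DUPLICATE_ATOM_PDB)
    return p


def make_point_topology(n_atoms, chain_id="A"):
    """n_atoms single-CA residues on one chain."""
    atoms = [
        Atom(serial=i + 1, name="CA", element="C", chain_id=chain_id, residue_index=i)
        for i in range(n_atoms)
    ]
    residues = [Residue(chain_id, i + 1, "", "ALA") for i in range(n_atoms)]
    return Topology(atoms, residues, {})


def make_trajectory(coords, chain_id="A"):
    """Trajectory over a one-atom-per-residue topology."""
    coords = np.asarray(coords, dtype=float)
    return Trajectory(coords, make_point_topology(coords.shape[1], chain_id))
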