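"""Shared fixtures: tiny hand-written structures and a small synthetic world.

All fixtures are generated programmatically; nothing is read from
checked-in data files.
"""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from akscore2 import synthetic
from akscore2.structio import LigandPose


MINI_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.155  -4.974  1.00  0.00           C
ATOM      4  O   ALA A   1      13.560   7.331  -5.836  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.247   4.690  -4.898  1.00  0.00           C
ATOM      6  H   ALA A   1      10.404   5.449  -6.730  1.00  0.00           H
ATOM      7  N   GLY A   2      12.638   7.899  -3.868  1.00  0.00           N
ATOM      8  CA  GLY A   2      13.594   8.975  -3.616  1.00  0.00           C
ATOM      9  C   GLY A   2      13.090  10.323  -4.115  1.00  0.00           C
ATOM     10  O   GLY A   2      11.898  10.505  -4.367  1.00  0.00           O
ATOM     11  N   SER A   3      14.010  11.273  -4.257  1.00  0.00           N
ATOM     12  CA  SER A   3      13.687  12.615  -4.727  1.00  0.00           C
ATOM     13  C   SER A   3      13.106  13.441  -3.585  1.00  0.00           C
ATOM     14  O   SER A   3      13.563  13.337  -2.445  1.00  0.00           O
ATOM     15  CB  SER A   3      14.932  13.316  -5.270  1.00  0.00           C
ATOM     16  OG  SER A   3      15.448  12.620  -6.394  1.00  0.00           O
TER
HETATM   17  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.500   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       1.700   0.300   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.200   1.300   0.000  1.00  0.00           C
END
"""


def embedded_mol(smiles: str, seed: int = 7) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    assert AllChem.EmbedMolecule(mol, randomSeed=seed) == 0
    return Chem.RemoveHs(mol)


def make_pose(smiles: str, seed: int = 7, pose_id: int = 0) -> LigandPose:
    return LigandPose(embedded_mol(smiles, seed), pose_id=pose_id)


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture
def benzene_pose():
    return make_pose("c1ccccc1")


@pytest.fixture
def aspirin_pose():
    return make_pose("CC(=O)Oc1ccccc1C(=O)O")


@pytest.fixture(scope="session")
def tiny_world():
    """A 6-target synthetic world shared across read-only tests."""
    return synthetic.generate_world(synthetic.WorldSpec(n_targets=6), seed=42)


@pytest.fixture(scope="session")
def tiny_world_dir(tmp_path_factory):
    """The same world written to disk (manifest + structures + physics)."""
    out = tmp_path_factory.mktemp("world")
    world = synthetic.generate_world(synthetic.WorldSpec(n_targets=4), seed=17,
                                     out_dir=out)
    return out, world


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
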