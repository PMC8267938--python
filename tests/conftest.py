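import numpy as np
import pytest

from clampmd.structure_io import MolecularStructure, Trajectory, atomic_mass
from clampmd.synthetic_dynamics import ToyModelConfig, build_toy_structure


def make_structure(atoms, chain="A"):
    """Build a MolecularStructure from (atom_name, res_name, res_id, element,
    (x, y, z)) tuples; hetero optional 6th entry."""
    n = len(atoms)
    return MolecularStructure(
        serial=np.arange(1, n + 1),
        atom_name=np.array([a[0] for a in atoms], dtype="U6"),
        res_name=np.array([a[1] for a in atoms], dtype="U4"),
        chain_id=np.array([chain] * n, dtype="U4"),
        res_id=np.array([a[2] for a in atoms], dtype=int),
        element=np.array([a[3] for a in atoms], dtype="U4"),
        mass=np.array([atomic_mass(a[3]) for a in atoms]),
        coord=np.array([a[4] for a in atoms], dtype=float),
        hetero=np.array([a[5] if len(a) > 5 else False for a in atoms]),
    )


def make_trajectory(structure, frames, dt=10.0):
    return Trajectory(topology=structure, coords=np.asarray(frames, float),
                      frame_interval_ps=dt)


@pytest.fixture(scope="session")
def toy_config():
    return ToyModelConfig()


@pytest.fixture(scope="session")
def toy_structure(toy_config):
    return build_toy_structure(toy_config)


# A phenylalanine with a full heavy-atom set plus backbone, for
# sidechain-class selection checks.
PHE_ATOMS = [
    ("N", "PHE", 183, "N", (0.0, 0.0, 0.0)),
    ("CA", "PHE", 183, "C", (1.4, 0.0, 0.0)),
    ("C", "PHE", 183, "C", (2.1, 1.3, 0.0)),
    ("O", "PHE", 183, "O", (1.5, 2.4, 0.0)),
    ("CB", "PHE", 183, "C", (2.2, -1.2, 0.5)),
    ("CG", "PHE", 183, "C", (3.5, -1.5, -0.1)),
    ("CD1", "PHE", 183, "C", (4.7, -1.0, 0.4)),
    ("CD2", "PHE", 183, "C", (3.6, -2.3, -1.2)),
    ("CE1", "PHE", 183, "C", (5.9, -1.3, -0.2)),
    ("CE2", "PHE", 183, "C", (4.8, -2.6, -1.8)),
    ("CZ", "PHE", 183, "C", (6.0, -2.1, -1.3)),
]


TWO_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
END
"""

# Alternate locations: B has the higher occupancy and must win; the second
# residue's altlocs tie on occupancy, so A must win.
ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA AGLY A   2       3.000   0.000   0.000  0.50  0.00           C
ATOM      4  CA BGLY A   2       4.000   0.000   0.000  0.50  0.00           C
END
"""

# Two models + a HETATM zinc and a water; element column blank on atom 2.
MULTIMODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00
ATOM      3  C   ALA A   1       2.200   1.300   0.000  1.00  0.00           C
HETATM    4 ZN    ZN A  90       8.000   8.000   8.000  1.00  0.00          ZN
HETATM    5  O   HOH A  91       9.000   9.000   9.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.600   0.000   0.000  1.00  0.00
ATOM      3  C   ALA A   1       2.300   1.300   0.000  1.00  0.00           C
HETATM    4 ZN    ZN A  90       8.100   8.000   8.000  1.00  0.00          ZN
HETATM    5  O   HOH A  91       9.100   9.000   9.000  1.00  0.00           O
ENDMDL
END
"""

BAD_COORD_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.5xx   0.000   0.000  1.00  0.00           C
END
"""
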