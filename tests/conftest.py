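import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from shapedock.mol_io import Atom, Molecule
from shapedock.synth import FixtureSpec, random_molecule

WATER_XYZ = """3
water
O 0.00000000 0.00000000 0.00000000
H 0.75700000 0.58600000 0.00000000
H -0.75700000 0.58600000 0.00000000
"""

# minimal V2000 block: 5 atoms, no bonds
SDF_5ATOMS = """probe
  handmade

  5  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7000    1.2000    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7000   -1.2000    0.3000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.2000    0.3000    1.4000 H   0  0  0  0  0  0  0  0  0  0  0  0
M  END
$$$$
"""

PDBQT_LIGAND = """ROOT
ATOM      1  C1  LIG A   1       0.000   0.000   0.000  0.00  0.00    +0.123 C
ATOM      2  O1  LIG A   1       1.500   0.000   0.000  0.00  0.00    -0.411 OA
ATOM      3  N1  LIG A   1      -0.700   1.200   0.000  0.00  0.00    -0.250 N
ATOM      4  H1  LIG A   1      -0.700  -1.200   0.300  0.00  0.00    +0.163 HD
ENDROOT
TORSDOF 0
"""


def build_molecule(elements, coords, name="fixture"):
    coords = np.asarray(coords, dtype=float)
    atoms = [
        Atom(i, el, f"{el}{i + 1}", coords[i]) for i, el in enumerate(elements)
    ]
    return Molecule(name, atoms)


def random_rigid_motion(rng, with_scale=False):
    """A proper rotation, a translation, and optionally a positive scale."""
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-20, 20, size=3)
    scale = float(rng.uniform(0.2, 5.0)) if with_scale else 1.0
    return rot, trans, scale


@pytest.fixture
def water_xyz(tmp_path):
    path = tmp_path / "water.xyz"
    path.write_text(WATER_XYZ)
    return path


@pytest.fixture
def sdf_file(tmp_path):
    path = tmp_path / "probe.sdf"
    path.write_text(SDF_5ATOMS)
    return path


@pytest.fixture
def pdbqt_file(tmp_path):
    path = tmp_path / "ligand.pdbqt"
    path.write_text(PDBQT_LIGAND)
    return path


@pytest.fixture
def chiral_molecule():
    # four distinct distances from each vertex: no proper rotation maps the
    # configuration onto its mirror image
    return build_molecule(
        ["C", "H", "N", "O"],
        [[0.0, 0.0, 0.0], [1.1, 0.0, 0.0], [0.0, 1.7, 0.0], [0.0, 0.0, 2.9]],
        name="chiral",
    )


@pytest.fixture
def organic_parent():
    spec = FixtureSpec(
        k=12,
        elements=("C", "C", "C", "O", "O", "O", "H", "H", "H", "H", "N", "H"),
        seed=20240317,
    )
    return random_molecule(spec)
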