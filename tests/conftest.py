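import numpy as np
import pytest

from ltk.core import Atom, MolecularSystem, Trajectory
from ltk.synthetic import ChannelSpec, make_channel_system
from ltk.tunnels import find_tunnels, free_radius_grid

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  O   HOH B   5       2.000   3.500  -1.250  1.00  0.00           O
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       2.000   0.000   0.000  1.00  0.00           N
ATOM      4  O   HOH B   9       3.000   0.000   0.000  1.00  0.00           O
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       1.000   1.000   1.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.500   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       1.500   1.000   1.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    path = tmp_path / "chains.pdb"
    path.write_text(TWO_CHAIN_PDB)
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    path = tmp_path / "models.pdb"
    path.write_text(TWO_MODEL_PDB)
    return path


def simple_atom(i, pos, **kw):
    defaults = dict(
        serial=i,
        name="CA",
        element="C",
        residue_id=i,
        residue_name="GLY",
        chain="A",
        position=np.asarray(pos, dtype=float),
    )
    defaults.update(kw)
    return Atom(**defaults)


@pytest.fixture
def small_system():
    atoms = [simple_atom(i + 1, [float(i), 0.0, 0.0]) for i in range(4)]
    return MolecularSystem(atoms)


@pytest.fixture(scope="session")
def open_channel():
    """Channel with one open cap, its free-radius grid, and its tunnels.

    Session-scoped: the grid build and Dijkstra searches dominate test
    runtime, and every consumer treats the results as read-only.
    """
    spec = ChannelSpec(inner_radius=3.0, length=20.0, cap_open=(True, False))
    system = make_channel_system(spec, seed=1)
    grid = free_radius_grid(system, spacing=0.6, padding=4.0, align_to=np.zeros(3))
    tunnels = find_tunnels(grid, np.zeros(3), probe_radius=1.2, max_tunnels=3)
    return spec, system, grid, tunnels


@pytest.fixture(scope="session")
def closed_channel():
    spec = ChannelSpec(inner_radius=3.0, length=20.0, cap_open=(False, False))
    system = make_channel_system(spec, seed=1)
    grid = free_radius_grid(system, spacing=0.6, padding=4.0, align_to=np.zeros(3))
    return spec, system, grid
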