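import numpy as np
import pytest

from mbrot import landscape, model_builder, toy_systems


@pytest.fixture(scope="session")
def toy_pair():
    """Default two-domain structure pair (12 degree rotation) with ground truth."""
    return toy_systems.make_two_state_toy()


@pytest.fixture(scope="session")
def params():
    return model_builder.ForceFieldParams()


@pytest.fixture(scope="session")
def merged_topology(toy_pair, params):
    rotated, unrotated, truth = toy_pair
    top_rot = model_builder.build_single_basin(
        rotated, params, bonds=truth.bonds, normalize=False
    )
    top_unrot = model_builder.build_single_basin(
        unrotated, params, bonds=truth.bonds, normalize=False
    )
    return model_builder.merge_basins(top_rot, top_unrot, rotated, unrotated, params)


@pytest.fixture(scope="session")
def basin_states():
    """State windows around the two minima of the double-well fixture."""
    return landscape.StateDefinition(unrotated=(-1.2, -0.8), rotated=(0.8, 1.2))


@pytest.fixture(scope="session")
def double_well_run():
    """Medium double-well Brownian run (a few dozen barrier crossings)."""
    spec = toy_systems.BrownianSpec(n_steps=8_000_000, seed=42)
    return toy_systems.make_brownian_trajectory(spec)


@pytest.fixture(scope="session")
def flat_run():
    """Free diffusion (no barrier) with known D for inference checks."""
    spec = toy_systems.BrownianSpec(
        barrier=0.0, n_steps=2_000_000, seed=7, save_every=10, reflect_at=3.0
    )
    return toy_systems.make_brownian_trajectory(spec)


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      10.000  20.000  30.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.500  20.000  30.000  1.00  0.00           C
ATOM      3  C   ALA A   1      12.000  21.400  30.000  1.00  0.00           C
END
"""

PDB_WITH_HYDROGENS = """\
ATOM      1  N   ALA A   1      10.000  20.000  30.000  1.00  0.00           N
ATOM      2  H   ALA A   1      10.500  19.200  30.000  1.00  0.00           H
ATOM      3  CA  ALA A   1      11.500  20.000  30.000  1.00  0.00           C
ATOM      4  HA  ALA A   1      11.800  19.000  30.000  1.00  0.00           H
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def hydrogen_pdb(tmp_path):
    path = tmp_path / "hydrogens.pdb"
    path.write_text(PDB_WITH_HYDROGENS)
    return path


@pytest.fixture
def four_atom_structure():
    rng = np.random.default_rng(0)
    from mbrot.structio import MolecularStructure

    return MolecularStructure(
        serials=[1, 2, 3, 4],
        names=["B1"] * 4,
        elements=["C"] * 4,
        residue_index=[1, 2, 3, 4],
        residue_names=["TOY"] * 4,
        chain_ids=["L"] * 4,
        positions=rng.normal(0.0, 1.0, (4, 3)),
        subunits=["LSU"] * 4,
    )
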