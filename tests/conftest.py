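import numpy as np
import pytest

from voxstab.fixtures import FixtureConfig, make_planted_dataset
from voxstab.structures import StructureModel
from voxstab.voxelize import GridSpec


def make_point_structure(coords, radii=None, flags=None, structure_id="pts"):
    """Minimal synthetic structure from raw coordinates (CA-like carbons)."""
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    model = StructureModel(
        serial=np.arange(1, n + 1),
        atom_name=np.array(["CA"] * n, dtype="U6"),
        element=np.array(["C"] * n, dtype="U4"),
        res_name=np.array(["ALA"] * n, dtype="U4"),
        res_id=np.arange(1, n + 1),
        ins_code=np.full(n, "", dtype="U2"),
        chain_id=np.full(n, "A", dtype="U4"),
        coord=coords,
        structure_id=structure_id,
    )
    if radii is not None:
        model.vdw_radius = np.asarray(radii, dtype=np.float64)
    if flags is not None:
        model.flags = np.asarray(flags, dtype=bool)
    return model


def random_point_structure(rng, n_atoms=30, box=6.0):
    """Random synthetic structure with random radii and property flags."""
    coords = rng.uniform(-box, box, size=(n_atoms, 3))
    radii = rng.choice([1.2, 1.52, 1.55, 1.7, 1.8], size=n_atoms)
    flags = rng.random((n_atoms, 7)) < 0.4
    flags[:, 6] = True  # occupancy covers all atoms
    return make_point_structure(coords, radii, flags)


@pytest.fixture(scope="session")
def small_planted():
    """Small planted dataset (direct + reverse) on the fast 8-voxel grid."""
    config = FixtureConfig(n_mutations=20, seed=42, grid=GridSpec(8))
    return make_planted_dataset(config)
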