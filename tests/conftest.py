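import numpy as np
import pytest

from permeopath import synthetic
from permeopath.model_io import Role


@pytest.fixture(scope="session")
def ideal_helix():
    return synthetic.build_ideal_helix(40)


@pytest.fixture(scope="session")
def contact_script():
    # disjoint per-frame sets; residue 9 is below the 5% site threshold but
    # dense inside its own contact window (pathway-only by design)
    return {
        1: set(range(0, 30)),
        4: set(range(50, 60)),
        7: set(range(30, 50)),
        9: {60, 62, 64, 66},
    }


@pytest.fixture(scope="session")
def scripted_trajectory(contact_script):
    protein = synthetic.make_spaced_residue_protein(10)
    return synthetic.make_scripted_ligand_trajectory(protein, contact_script, n_frames=100)


@pytest.fixture(scope="session")
def ligand_selection(scripted_trajectory):
    return scripted_trajectory.topology.indices(role=Role.ligand)


@pytest.fixture(scope="session")
def two_domain_trajectory():
    # 16-residue rigid core, 8-residue arm swung 120 deg in the last frame
    return synthetic.make_two_domain_ensemble(
        16, 8, n_frames=3, arm_rotation=[0.0, 0.0, 120.0], noise_sigma=0.0, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
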