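import numpy as np
import pytest

from lmphmap import SyntheticCohortConfig, generate_volume_cohort, generate_voxel_table, read_cohort


@pytest.fixture(scope="session")
def small_table():
    """Voxel table of a 6-patient cohort with separated class distributions."""
    config = SyntheticCohortConfig(n_patients=6, voxels_per_patient=(400, 800), seed=3)
    return generate_voxel_table(config)


@pytest.fixture(scope="session")
def volume_cohort(tmp_path_factory):
    """A 4-patient NIfTI cohort on disk plus its loaded PatientVolumeSets."""
    out = tmp_path_factory.mktemp("cohort")
    config = SyntheticCohortConfig(n_patients=4, seed=11, grid_shape=(32, 32, 32))
    manifest = generate_volume_cohort(config, out)
    return manifest, read_cohort(manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
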