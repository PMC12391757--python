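import numpy as np
import pytest

from netlesion.synthetic_data import SyntheticConfig, generate_dataset
from netlesion.volume_io import BrainMask, VolumeGrid


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale study: small grid, 3 distributed networks, 8 subjects."""
    return SyntheticConfig(
        grid_shape=(12, 14, 12),
        n_networks=3,
        n_vascular_territories=4,
        n_tracts=3,
        n_subjects=8,
        n_timepoints=60,
        lesion_volume_voxels=(10, 40),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture
def grid8():
    return VolumeGrid.isotropic((8, 8, 8), 1.0)


@pytest.fixture
def full_mask8(grid8):
    return BrainMask(grid=grid8, data=np.ones((8, 8, 8), dtype=np.uint8))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
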