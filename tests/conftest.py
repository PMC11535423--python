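import numpy as np
import pytest

from cellquant.spots import SpheroidRadii, SpotCallingConfig
from cellquant.synth import StackSimParams, generate_smfish_stack


@pytest.fixture(scope="session")
def high_snr_stack():
    """A simulated stack with 30 bright, well-separated spots (6 cells x 5)."""
    params = StackSimParams(
        n_cells=6, n_spots=5, spot_amplitude=100.0, seed=42, shape=(20, 128, 128)
    )
    return generate_smfish_stack(params)


@pytest.fixture(scope="session")
def strict_config():
    """Spot-calling config with the effect-size threshold at the top of the
    manually-chosen range, as used with bright probes."""
    return SpotCallingConfig(effect_size_threshold=1.0)


@pytest.fixture()
def small_radii():
    """Compact spheroid radii (voxel units) for hand-built small stacks."""
    return SpheroidRadii(r_xy_um=2.0, r_z_um=2.0, r_xy_vox=2.0, r_z_vox=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
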