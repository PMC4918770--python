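import numpy as np
import pytest

from cnswave import synthetic_data as sd
from cnswave.volume_io import VolumeSeries


@pytest.fixture(scope="session")
def small_cfg():
    """Compact phantom used by rendering-heavy tests."""
    return sd.PhantomConfig(
        shape=(96, 48, 24),
        duration=60.0,
        n_forward=2,
        n_backward=1,
        refractory_s=12.0,
        schedule_start_s=15.0,
        noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    return sd.make_phantom(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return sd.simulate_schedule(small_cfg)


@pytest.fixture(scope="session")
def rendered(small_cfg, small_phantom, small_truth):
    """(viewA, viewB, dff_truth) for the compact noise-free phantom."""
    return sd.render(small_phantom, small_truth, small_cfg)


@pytest.fixture()
def ramp_series():
    """Tiny deterministic 8x8x4x5 ramp volume."""
    data = np.arange(8 * 8 * 4 * 5, dtype=np.uint16).reshape(8, 8, 4, 5)
    return VolumeSeries(data, voxel_size=(2.0, 2.0, 4.0), frame_interval=0.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
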