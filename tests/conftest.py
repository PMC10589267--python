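import numpy as np
import pytest

from parashim.config import WorldConfig
from parashim.presets import reduced_run_config
from parashim.spectrometer import build_spectrometer


@pytest.fixture(scope="session")
def default_world():
    """Full two-channel six-shim probe with receiver noise."""
    return build_spectrometer(WorldConfig(), seed=7)


@pytest.fixture(scope="session")
def quiet_world():
    """Full probe with the receiver idealized (no noise/phase/leak)."""
    cfg = WorldConfig()
    cfg.receiver.snr = None
    cfg.receiver.leak_coeff = 0.0
    return build_spectrometer(cfg, seed=7)


@pytest.fixture(scope="session")
def reduced_cfg():
    """Desk-scale learning condition (2 zonal shims, 512-bin spectra)."""
    return reduced_run_config(seed=1, n_samples=100)


@pytest.fixture(scope="session")
def reduced_world(reduced_cfg):
    return build_spectrometer(reduced_cfg.world, seed=reduced_cfg.seed)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
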