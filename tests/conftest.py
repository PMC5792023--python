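import numpy as np
import pytest

from fociquant.config import SimulationConfig


@pytest.fixture
def small_config():
    """Compact field for fast simulations."""
    return SimulationConfig(field_height_px=128, field_width_px=128)


@pytest.fixture
def quiet_config():
    """Noise-free, bleach-free config for photometric checks."""
    return SimulationConfig(
        field_height_px=96, field_width_px=96,
        autofluor_amplitude_au=0.0, read_noise_sd_au=0.0,
        tau_bleach_s=1e12, return_rate_per_s=0.0, n_frames_rapid=3,
        f_tight=0.0, f_loose=0.0, f_dispersed=1.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
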