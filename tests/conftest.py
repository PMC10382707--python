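import numpy as np
import pytest

from audiogain import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_params():
    """Zero-noise waveform model: fully deterministic templates."""
    return synth.WaveformModelParams(noise_sd_uv=0.0, n_trials=4)


@pytest.fixture
def small_cohort_config():
    return synth.CohortConfig(n_wt=6, n_mut=6, seed=11)


@pytest.fixture
def square_geometry():
    """1 mm x 1 mm region: area exactly 1 mm^2."""
    return synth.GeometrySpec(
        region_xy=((0.0, -1000.0), (1000.0, -1000.0), (1000.0, 0.0), (0.0, 0.0)),
        pia_xy=((-100.0, 0.0), (1100.0, 0.0)),
        wm_xy=((-100.0, -1000.0), (1100.0, -1000.0)),
    )
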