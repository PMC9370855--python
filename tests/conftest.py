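import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gaitpredict import SynthConfig, synthesize


@pytest.fixture(scope="session")
def straight_sway_walk():
    """Noiseless 10 s straight walk with sway and speed oscillation."""
    cfg = SynthConfig(
        path_kind="straight",
        mean_speed=1.2,
        stride_hz=1.0,
        noise_sd=0.0,
        duration=10.0,
        seed=3,
    )
    return synthesize(cfg)


@pytest.fixture(scope="session")
def circle_sway_walk():
    """Noiseless single-turn circle walk with sway."""
    cfg = SynthConfig(
        path_kind="circle",
        radius_m=1.5,
        mean_speed=1.0,
        stride_hz=1.0,
        noise_sd=0.0,
        seed=4,
    )
    return synthesize(cfg)


@pytest.fixture(scope="session")
def clean_straight_walk():
    """Straight constant-speed walk with no perturbation at all."""
    cfg = SynthConfig(
        path_kind="straight",
        mean_speed=1.2,
        stride_hz=1.0,
        sway_amp=0.0,
        vel_osc_amp=0.0,
        pelvis_osc_amp=0.0,
        noise_sd=0.0,
        duration=6.0,
        seed=5,
    )
    return synthesize(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
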