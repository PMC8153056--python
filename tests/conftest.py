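import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cardioaudio.synthgen import SimulationConfig, make_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def layout16():
    return make_layout(16)


@pytest.fixture(scope="session")
def layout128():
    return make_layout(128)


@pytest.fixture
def small_config():
    """Small but structurally complete study configuration."""
    return SimulationConfig(n_subjects=2, n_channels=16, n_blocks=2,
                            trials_per_block=8, tones_per_trial=(5, 6),
                            rest_duration_s=20.0, blink_rate_hz=0.0, seed=7)
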