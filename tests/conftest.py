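import numpy as np
import pytest

from calnet import StimulusProtocol
from calnet.synthetic import DynamicsParams


@pytest.fixture
def full_protocol() -> StimulusProtocol:
    """The standard 750-s session at 3.3 Hz."""
    return StimulusProtocol()


@pytest.fixture
def short_protocol() -> StimulusProtocol:
    """A compressed 90-s session for fast unit tests."""
    return StimulusProtocol(
        fs=3.3,
        baseline_span=30.0,
        stim_onset=40.0,
        stim_duration=10.0,
        kcl_onset=70.0,
        kcl_duration=10.0,
        total_duration=90.0,
    )


@pytest.fixture
def quiet_dyn() -> DynamicsParams:
    """Noise-free, bleach-free dynamics with no events: traces stay at f0."""
    return DynamicsParams(base_rate=0.0, bleach_slope=0.0, noise_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
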