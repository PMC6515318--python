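import numpy as np
import pytest

from distalemg.synth import MixingModel, SynthConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_recording():
    """A 2 s calibration recording at 2 kHz, shared across read-only tests."""
    return generate_recording(SynthConfig(duration_s=2.0), seed=42)


@pytest.fixture
def quiet_mixing():
    """Low-noise mixing for tests that need a clean linear-ish relationship."""
    return MixingModel(noise_std=0.01, powerline_amplitude=0.01, motion_amplitude=0.02)
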