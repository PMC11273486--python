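import numpy as np
import pytest

from nirsbreath import nirs_io, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_recording():
    """Clean 4-channel sinusoid, 8 s at 120 Hz."""
    t = np.arange(960) / 120.0
    base = np.sin(2 * np.pi * 0.25 * t)
    values = np.stack([base, -0.5 * base, 1.2 * base, -0.7 * base])
    return nirs_io.NIRSRecording(values=values, participant_id="p0",
                                 task_label="normal")


@pytest.fixture(scope="session")
def small_split():
    """Small but participant-diverse synthetic dataset (shared across tests)."""
    return synth.make_dataset(
        synth.SimConfig(n_participants=4, duration_per_task=20.0, stride=192,
                        n_test_participants=1, seed=99)
    )
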