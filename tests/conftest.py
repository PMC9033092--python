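import warnings

import numpy as np
import pytest

from wicaeeg import SimulationConfig, simulate_eeg
from wicaeeg.preproc import Recording


@pytest.fixture(autouse=True)
def _quiet_sample_size_warnings():
    # small desk-scale simulations trip the n_samples >= 20*n_channels^2
    # advisory; it is exercised explicitly in test_ica
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* samples for .* channels")
        yield


@pytest.fixture(scope="session")
def small_clean_truth():
    """Artifact-free 8-channel recording with exact ground truth."""
    cfg = SimulationConfig(
        n_channels=8, fs=250.0, duration=40.0,
        blink_amplitude=0.0, muscle_burst_rate=0.0,
        line_noise_amplitude=0.0, sensor_noise_rms=0.0,
        mixing_seed=11, noise_seed=11,
    )
    return simulate_eeg(cfg)


@pytest.fixture(scope="session")
def small_artifact_truth():
    """8-channel recording with the full default artifact mix."""
    cfg = SimulationConfig(
        n_channels=8, fs=250.0, duration=40.0, mixing_seed=21, noise_seed=21,
    )
    return simulate_eeg(cfg)


@pytest.fixture()
def sine_recording():
    def make(freqs, fs=500.0, duration=10.0, n_channels=2, amplitude=1.0):
        t = np.arange(int(duration * fs)) / fs
        freqs = np.atleast_1d(freqs)
        row = sum(amplitude * np.sin(2 * np.pi * f * t) for f in freqs)
        data = np.tile(row, (n_channels, 1))
        return Recording(data=data, fs=fs, channel_labels=[f"CH{i}" for i in range(n_channels)])

    return make
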