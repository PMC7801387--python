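import numpy as np
import pytest

from bseeg_tda import ArtifactRates, SimulationConfig, Window, simulate_eeg

NO_ARTIFACTS = ArtifactRates(emg=0, ecg=0, drift=0, flatline=0)


def make_window(samples, duration, sampling_rate, start_index=0):
    return Window(start_index=start_index, duration=duration,
                  sampling_rate=sampling_rate, samples=samples)


def sine_window(freqs_amps, duration=4.0, sampling_rate=128.0, phase=0.0):
    """Window holding a sum of sinusoids, e.g. [(3, 2.0), (10, 1.0)]."""
    t = np.arange(round(duration * sampling_rate)) / sampling_rate
    x = np.zeros_like(t)
    for f, a in freqs_amps:
        x = x + a * np.sin(2 * np.pi * f * t + phase)
    return make_window(x, duration, sampling_rate)


@pytest.fixture
def clean_slowed_record():
    return simulate_eeg(SimulationConfig(
        duration=40.0, slowing_index=1.0, artifact_rates=NO_ARTIFACTS, seed=11))


@pytest.fixture
def clean_normal_record():
    return simulate_eeg(SimulationConfig(
        duration=40.0, slowing_index=0.0, artifact_rates=NO_ARTIFACTS, seed=12))
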