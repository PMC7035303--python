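import numpy as np
import pytest

from flowpulse import CohortParams, FlowWaveform, WaveformParams, generate_cohort_frame
from flowpulse.phantom import generate_waveform


def make_sine_waveform(n=1000, q0=5.0, amplitude=2.0, period=1.0, phase=0.0):
    """Q(t) = q0 + A sin(2π t / T + phase), sampled at n uniform times."""
    t = np.arange(n) / n * period
    q = q0 + amplitude * np.sin(2 * np.pi * t / period + phase)
    return FlowWaveform(t, q, period)


def make_random_waveform(rng, n=None):
    """A positive, irregularly sampled random waveform."""
    n = n or int(rng.integers(5, 50))
    rr = float(rng.uniform(0.6, 1.2))
    t = np.sort(rng.uniform(0, rr, n))
    t += (rr - t[-1]) * 0.01  # keep strictly inside [0, rr)
    while np.any(np.diff(t) <= 0):
        t = np.sort(rng.uniform(0, rr * 0.99, n))
    q = rng.uniform(1.0, 8.0) + rng.normal(0, 1.5, n)
    return FlowWaveform(t, q, rr)


@pytest.fixture
def sine_waveform():
    return make_sine_waveform


@pytest.fixture
def ica_like_waveform():
    """A realistic 20-phase ICA waveform: dicrotic wave plus noise."""
    params = WaveformParams(dicrotic_amplitude=0.8, noise_sd=0.1, seed=42)
    return generate_waveform(params, n_samples=20, artery="ICA", side="left")


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-subject synthetic cohort shared across tests."""
    frame, truth = generate_cohort_frame(CohortParams(n_subjects=400, seed=3))
    return frame, truth
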