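import numpy as np
import pytest

from mitfopt.io_fixture import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_epochs(
    rng,
    n_trials=6,
    n_channels=4,
    n_samples=100,
    sfreq=125.0,
    t0=0.0,
    n_classes=2,
):
    """Random valid EpochSet with alternating labels."""
    data = rng.standard_normal((n_trials, n_channels, n_samples))
    labels = np.arange(n_trials) % n_classes
    names = [f"CH{i:02d}" for i in range(n_channels)]
    return EpochSet(data=data, labels=labels, sfreq=sfreq, channel_names=names, t0=t0)


@pytest.fixture
def tiny_epochs(rng):
    return make_epochs(rng)


def sine_epochs(freq, sfreq=250.0, duration=4.0, n_trials=1, n_channels=1, amplitude=1.0, t0=0.0):
    """Pure sinusoid epochs for filter-response oracles."""
    n = int(round(duration * sfreq))
    t = np.arange(n) / sfreq
    x = amplitude * np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (n_trials, n_channels, 1))
    labels = np.arange(n_trials) % 2
    names = [f"CH{i:02d}" for i in range(n_channels)]
    return EpochSet(data=data, labels=labels, sfreq=sfreq, channel_names=names, t0=t0)


def steady_amplitude(epochs, edge_s=0.5):
    """RMS-based amplitude estimate excluding filter edge transients."""
    i = int(round(edge_s * epochs.sfreq))
    core = epochs.data[..., i:-i] if i > 0 else epochs.data
    return float(np.sqrt(2.0 * np.mean(core**2)))
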