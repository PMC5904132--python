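import numpy as np
import pytest

from rhen.preproc import EpochSet
from rhen.synth import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_epochs(data, sfreq=250.0, labels=None, rt=None):
    """Wrap raw (trials, channels, samples) data in an EpochSet with stub metadata."""
    data = np.asarray(data, float)
    n = data.shape[0]
    if labels is None:
        labels = np.array(["error", "correct"] * ((n + 1) // 2))[:n]
    if rt is None:
        rt = np.full(n, 500.0)
    return EpochSet(data=data, sfreq=sfreq, labels=labels, rt=rt)


@pytest.fixture
def tone_epochs():
    """Single trial/channel sinusoid factory: (freq_hz, sfreq, seconds) -> EpochSet."""

    def _make(freq, sfreq=250.0, seconds=2.0):
        t = np.arange(int(seconds * sfreq)) / sfreq
        return make_epochs(np.sin(2 * np.pi * freq * t)[None, None, :], sfreq=sfreq)

    return _make


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset shared by read-only tests."""
    cfg = SimConfig(
        n_channels=16,
        n_dipoles=40,
        n_trials_per_class=5,
        active_dipoles=(10, 11, 30),
        seed=42,
    )
    return cfg, *simulate_dataset(cfg)
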