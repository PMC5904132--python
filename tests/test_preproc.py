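"""Preprocessing contracts: amplitude-based trial rejection, zero-phase filtering,
re-referencing, and rhythm-band decomposition."""

import numpy as np
import pytest
from scipy import signal

from rhen.preproc import (
    BANDS,
    bandpass_epochs,
    extract_bands,
    reject_artifact_trials,
    rereference,
)
from rhen.synth import make_leadfield

from conftest import make_epochs


def total_power(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestArtifactRejection:
    def test_removes_trial_exceeding_75uv(self, rng):
        data = rng.normal(0, 5, size=(3, 4, 100))
        data[1, 2, 50] = 80.0  # one 80 µV excursion
        epochs = make_epochs(data)
        out = reject_artifact_trials(epochs, 75.0)
        assert out.n_trials == 2
        np.testing.assert_array_equal(out.data[0], data[0])
        np.testing.assert_array_equal(out.data[1], data[2])
        assert list(out.labels) == [epochs.labels[0], epochs.labels[2]]

    def test_noop_when_all_bounded(self, rng):
        data = rng.uniform(-10, 10, size=(4, 3, 50))
        out = reject_artifact_trials(make_epochs(data), 75.0)
        np.testing.assert_array_equal(out.data, data)

    def test_infinite_threshold_is_identity(self, rng):
        data = rng.normal(0, 100, size=(3, 2, 50))
        out = reject_artifact_trials(make_epochs(data), np.inf)
        assert out.n_trials == 3

    def test_all_rejected_raises(self, rng):
        data = rng.normal(0, 100, size=(3, 2, 500))
        with pytest.raises(ValueError, match="all"):
            reject_artifact_trials(make_epochs(data), 1e-6)

    def test_labels_and_rt_stay_aligned(self, rng):
        data = rng.normal(0, 5, size=(6, 2, 50))
        data[[0, 3], 0, 0] = 200.0
        labels = np.array(["error", "correct"] * 3)
        rt = np.arange(6, dtype=float) * 100 + 100
        out = reject_artifact_trials(make_epochs(data, labels=labels, rt=rt), 75.0)
        np.testing.assert_array_equal(out.rt, rt[[1, 2, 4, 5]])
        np.testing.assert_array_equal(out.labels, labels[[1, 2, 4, 5]])


class TestBandpass:
    def test_50hz_attenuated(self, tone_epochs):
        ep = tone_epochs(50.0)
        out = bandpass_epochs(ep, 0.1, 30.0)
        assert total_power(out.data) <= 0.01 * total_power(ep.data)

    def test_10hz_preserved(self, tone_epochs):
        ep = tone_epochs(10.0)
        out = bandpass_epochs(ep, 0.1, 30.0)
        assert np.max(np.abs(out.data)) == pytest.approx(np.max(np.abs(ep.data)), rel=0.05)

    def test_dc_removed(self):
        ep = make_epochs(np.full((1, 1, 500), 7.0))
        out = bandpass_epochs(ep, 0.1, 30.0)
        assert abs(out.data.mean()) < abs(ep.data.mean()) * 0.5

    def test_rejects_high_above_nyquist(self, tone_epochs):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_epochs(tone_epochs(10.0), 0.1, 200.0)

    def test_zero_phase_no_latency_shift(self):
        # band-limited pulse: peak latency must not move by ≥ 1 sample
        sfreq = 250.0
        t = np.arange(500) / sfreq
        x = np.exp(-((t - 1.0) ** 2) / 0.02) * np.sin(2 * np.pi * 10 * (t - 1.0))
        out = bandpass_epochs(make_epochs(x[None, None, :], sfreq=sfreq), 0.1, 30.0)
        assert abs(int(np.argmax(np.abs(out.data[0, 0]))) - int(np.argmax(np.abs(x)))) < 1


class TestRereference:
    def test_average_zeroes_channel_mean(self, rng):
        out = rereference(make_epochs(rng.normal(5, 3, (2, 6, 40))), "average")
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-10)

    def test_average_idempotent(self, rng):
        ep = make_epochs(rng.normal(0, 3, (2, 6, 40)))
        once = rereference(ep, "average")
        twice = rereference(once, "average")
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_rest_requires_leadfield(self, rng):
        with pytest.raises(ValueError, match="leadfield"):
            rereference(make_epochs(rng.normal(0, 1, (1, 4, 20))), "rest")

    def test_rest_recovers_infinite_reference_better_than_cz(self, rng):
        # simulate infinite-reference potentials, record against Cz (channel 0),
        # REST output should correlate better with the truth than the raw recording
        A = make_leadfield(16, 64, seed=5)
        n_trials, n_samp = 12, 100
        wins_rest = 0
        for tr in range(n_trials):
            s = rng.standard_normal((64, n_samp))
            v_inf = A @ s
            v_cz = v_inf - v_inf[0:1, :]  # referenced at channel 0
            ep = make_epochs(v_cz[None], labels=np.array(["error"]), rt=np.array([1.0]))
            v_rest = rereference(ep, "rest", leadfield=A).data[0]
            c_rest = np.corrcoef(v_rest.ravel(), v_inf.ravel())[0, 1]
            c_cz = np.corrcoef(v_cz.ravel(), v_inf.ravel())[0, 1]
            wins_rest += c_rest > c_cz
        assert wins_rest > n_trials / 2


class TestExtractBands:
    @pytest.mark.parametrize("freq, band", [(6.0, "theta"), (10.0, "alpha"), (20.0, "beta")])
    def test_tone_dominates_its_band(self, tone_epochs, freq, band):
        parts = extract_bands(tone_epochs(freq))
        powers = {b: total_power(e.data) for b, e in parts.items()}
        assert powers[band] >= 0.9 * sum(powers.values())

    def test_white_noise_power_partition(self, rng):
        sfreq = 250.0
        x = rng.standard_normal((1, 1, 5000))
        ep = make_epochs(x, sfreq=sfreq)
        parts = extract_bands(ep)
        f, p = signal.periodogram(x[0, 0], fs=sfreq)
        target = p[(f >= 4) & (f <= 30)].sum()
        got = 0.0
        for e in parts.values():
            fe, pe = signal.periodogram(e.data[0, 0], fs=sfreq)
            got += pe[(fe >= 4) & (fe <= 30)].sum()
        assert got == pytest.approx(target, rel=0.10)

    def test_wavelet_backend_agrees_on_band_dominance(self, tone_epochs):
        parts = extract_bands(tone_epochs(10.0), method="wavelet")
        powers = {b: total_power(e.data) for b, e in parts.items()}
        assert powers["alpha"] >= 0.8 * sum(powers.values())

    def test_requires_adequate_sfreq(self, rng):
        ep = make_epochs(rng.standard_normal((1, 1, 200)), sfreq=63.0)
        with pytest.raises(ValueError):
            extract_bands(ep)
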