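"""Connectivity contracts: region averaging, Kalman coefficient tracking, SBC order
selection, transfer function, ADTF normalization/integration, surrogates, net flow."""

import numpy as np
import pytest

from rhen.network import (
    adtf_normalize,
    fit_mvaar_kalman,
    integrate_adtf,
    net_flow,
    phase_randomize,
    region_time_series,
    select_order_sbc,
    surrogate_null,
    transfer_function,
)
from rhen.synth import simulate_mvar_nodes


def chain3_coeffs():
    co = np.zeros((1, 3, 3))
    co[0] = [[0.5, 0.0, 0.0], [0.5, 0.5, 0.0], [0.0, 0.5, 0.5]]
    return co


class TestRegionTimeSeries:
    def test_singleton_region_passthrough(self, rng):
        S = rng.normal(0, 1, (5, 40))
        out = region_time_series(S, [[2]])
        np.testing.assert_array_equal(out[0], S[2])

    def test_identical_waveforms_mean_unchanged(self, rng):
        w = rng.normal(0, 1, 30)
        S = np.stack([w, w, -w])
        np.testing.assert_allclose(region_time_series(S, [[0, 1]])[0], w)

    def test_antiphase_pair_cancels(self, rng):
        w = rng.normal(0, 1, 30)
        S = np.stack([w, -w])
        np.testing.assert_allclose(region_time_series(S, [[0, 1]])[0], 0.0, atol=1e-12)

    def test_empty_or_overlapping_regions_rejected(self, rng):
        S = rng.normal(0, 1, (4, 20))
        with pytest.raises(ValueError, match="empty"):
            region_time_series(S, [[0], []])
        with pytest.raises(ValueError, match="disjoint"):
            region_time_series(S, [[0, 1], [1, 2]])


class TestKalmanFit:
    def test_recovers_constant_cross_coefficient(self):
        co = np.zeros((1, 2, 2))
        co[0, 0, 0] = 0.5
        co[0, 1, 0] = 0.5
        X = simulate_mvar_nodes(co, 2000, seed=4)
        fit = fit_mvaar_kalman(X, p=1)
        avg = fit.coeffs[fit.burn_in :].mean(axis=0)
        assert abs(avg[0, 1, 0] - 0.5) < 0.1
        assert abs(avg[0, 0, 0] - 0.5) < 0.1

    def test_independent_noise_gives_null_cross_terms(self, rng):
        X = rng.standard_normal((2, 2000))
        fit = fit_mvaar_kalman(X, p=1)
        avg = fit.coeffs[fit.burn_in :].mean(axis=0)
        assert abs(avg[0, 0, 1]) < 0.1
        assert abs(avg[0, 1, 0]) < 0.1

    def test_deterministic(self, rng):
        X = rng.standard_normal((3, 400))
        f1 = fit_mvaar_kalman(X, p=2)
        f2 = fit_mvaar_kalman(X, p=2)
        np.testing.assert_array_equal(f1.coeffs, f2.coeffs)

    def test_rejects_nonfinite_and_short_input(self, rng):
        X = rng.standard_normal((2, 300))
        X[0, 5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_mvaar_kalman(X, p=1)
        with pytest.raises(ValueError, match="short"):
            fit_mvaar_kalman(rng.standard_normal((2, 30)), p=2)

    def test_batched_matches_single(self, rng):
        X = rng.standard_normal((2, 3, 300))
        fits = fit_mvaar_kalman(X, p=1)
        single = fit_mvaar_kalman(X[1], p=1)
        np.testing.assert_allclose(fits[1].coeffs, single.coeffs, atol=1e-12)


class TestOrderSelection:
    def test_var2_recovered_majority(self):
        co = np.zeros((2, 2, 2))
        co[0] = [[0.4, 0.2], [0.0, 0.3]]
        co[1] = [[-0.4, 0.0], [0.2, -0.35]]
        hits = 0
        for s in range(10):
            X = simulate_mvar_nodes(co, 3000, seed=s)
            hits += select_order_sbc(X, p_max=6) == 2
        assert hits >= 8

    def test_white_noise_selects_minimum(self, rng):
        hits = 0
        for s in range(5):
            X = np.random.default_rng(s).standard_normal((2, 1500))
            hits += select_order_sbc(X, p_max=5) == 1
        assert hits >= 3

    def test_range_contract(self, rng):
        X = rng.standard_normal((2, 800))
        p = select_order_sbc(X, p_max=4)
        assert 1 <= p <= 4

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="short"):
            select_order_sbc(rng.standard_normal((3, 40)), p_max=12)


class TestTransferFunction:
    def _fit_from_coeffs(self, coeffs, T=200):
        """Build a constant-coefficient MVAARFit without fitting."""
        from rhen.network import MVAARFit

        p, n, _ = coeffs.shape
        tensor = np.broadcast_to(coeffs, (T, p, n, n)).copy()
        return MVAARFit(coeffs=tensor, order=p, uc=1e-3, residuals=np.zeros((T, n)))

    def test_zero_coefficients_give_identity(self):
        fit = self._fit_from_coeffs(np.zeros((1, 3, 3)))
        H, _ = transfer_function(fit, np.arange(1.0, 30), 250.0)
        np.testing.assert_allclose(H, np.broadcast_to(np.eye(3), H.shape), atol=1e-12)

    def test_decoupled_system_diagonal(self):
        co = np.zeros((1, 2, 2))
        np.fill_diagonal(co[0], 0.6)
        fit = self._fit_from_coeffs(co)
        H, _ = transfer_function(fit, np.arange(1.0, 30), 250.0)
        np.testing.assert_allclose(H[..., 0, 1], 0.0, atol=1e-12)
        np.testing.assert_allclose(H[..., 1, 0], 0.0, atol=1e-12)

    def test_coupled_system_matches_analytic_spectrum(self):
        # 2-node, lag-1: analytic H = (I − A e^{-iω})⁻¹ evaluated by hand
        co = np.zeros((1, 2, 2))
        co[0] = [[0.5, 0.0], [0.4, 0.3]]
        fit = self._fit_from_coeffs(co)
        freqs = np.array([5.0, 11.0])
        sfreq = 100.0
        H, _ = transfer_function(fit, freqs, sfreq)
        for fi, f in enumerate(freqs):
            z = np.exp(-2j * np.pi * f / sfreq)
            expected = np.linalg.inv(np.eye(2) - co[0] * z)
            np.testing.assert_allclose(H[0, fi], expected, atol=1e-12)
        assert np.all(np.abs(H[..., 1, 0]) > 0)
        np.testing.assert_allclose(np.abs(H[..., 0, 1]), 0.0, atol=1e-12)


class TestAdtf:
    def test_identity_transfer_gives_identity_pattern(self):
        H = np.broadcast_to(np.eye(3), (4, 6, 3, 3))
        iota = adtf_normalize(H)
        np.testing.assert_allclose(iota, H.real, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        H = rng.normal(0, 1, (3, 5, 4, 4)) + 1j * rng.normal(0, 1, (3, 5, 4, 4))
        iota = adtf_normalize(H)
        np.testing.assert_allclose(iota.sum(axis=-1), 1.0, atol=1e-10)

    def test_matches_two_line_oracle(self, rng):
        H = rng.normal(0, 1, (2, 3, 3, 3)) + 1j * rng.normal(0, 1, (2, 3, 3, 3))
        P = np.abs(H) ** 2
        oracle = P / P.sum(axis=-1, keepdims=True)
        np.testing.assert_allclose(adtf_normalize(H), oracle, atol=1e-12)

    def test_integrate_constant_and_halves(self):
        freqs = np.arange(1.0, 31.0)
        adtf = np.full((2, len(freqs), 2, 2), 0.37)
        out = integrate_adtf(adtf, freqs, 4, 30)
        np.testing.assert_allclose(out, 0.37, atol=1e-12)
        mixed = adtf.copy()
        in_band = (freqs >= 4) & (freqs <= 30)
        half = np.flatnonzero(in_band)[: in_band.sum() // 2]
        # not an even count guard: construct explicit half/half band values
        vals = np.zeros(len(freqs))
        vals[np.flatnonzero(in_band)[::2]] = 1.0
        mixed[..., :, 0, 0] = vals
        out2 = integrate_adtf(mixed, freqs, 4, 30)
        frac = vals[in_band].mean()
        np.testing.assert_allclose(out2[..., 0, 0], frac, atol=1e-12)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            integrate_adtf(np.ones((1, 3, 2, 2)), np.array([1.0, 2.0, 3.0]), 50, 60)

    def test_net_flow_antisymmetry(self):
        assert net_flow(0.6, 0.2) == pytest.approx(0.4)
        assert net_flow(0.2, 0.6) == pytest.approx(-0.4)
        assert net_flow(0.3, 0.3) == 0.0


class TestSurrogates:
    def test_amplitude_spectra_preserved(self, rng):
        X = rng.standard_normal((3, 400))
        S = phase_randomize(X, 4, seed=2)
        orig = np.abs(np.fft.rfft(X, axis=-1))
        for b in range(4):
            got = np.abs(np.fft.rfft(S[b], axis=-1))
            dev = np.abs(got - orig) / np.maximum(orig, 1e-300)
            assert dev.max() < 1e-8

    def test_surrogates_are_real_and_distinct(self, rng):
        X = rng.standard_normal((2, 256))
        S = phase_randomize(X, 2, seed=0)
        assert np.isrealobj(S)
        assert not np.allclose(S[0], S[1])

    def test_coupled_edge_detected_null_edge_not(self):
        co = np.zeros((1, 2, 2))
        co[0] = [[0.5, 0.0], [0.5, 0.3]]
        X = simulate_mvar_nodes(co, 1500, seed=3)
        null, theta2, times = surrogate_null(
            X, p=1, sfreq=250.0, n_surrogates=100, seed=7
        )
        frac_true = (theta2[:, 1, 0] > null.thresholds[1, 0]).mean()
        frac_false = (theta2[:, 0, 1] > null.thresholds[0, 1]).mean()
        assert frac_true >= 0.8
        assert frac_false < 0.5
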