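"""Time-varying directed connectivity: Kalman-tracked MVAAR and the adaptive
directed transfer function (ADTF), with phase-randomization surrogate testing.

The node series follow a time-varying VAR, X(t) = Σ_k w_k(t) X(t−k) + ε(t), whose
coefficients are tracked recursively (a Kalman/RLS scheme with a small update
coefficient controlling adaptation speed).  In the frequency domain
A(f,t) = I − Σ_k w_k(t) e^{−j2πfkΔt} and H(f,t) = A(f,t)⁻¹; the normalized ADTF
ι²_ij(f,t) = |H_ij|² / Σ_k |H_ik|² quantifies the directed influence j→i and sums to
1 over sources for each receiver.  The integrated ADTF ϑ²_ij(t) averages ι² over the
4–30 Hz band.  Significance comes from surrogates that randomize each node's Fourier
phases independently (preserving autospectra, destroying cross-node phase relations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MVAARFit",
    "TVNetwork",
    "SurrogateNull",
    "region_time_series",
    "fit_mvaar_kalman",
    "select_order_sbc",
    "transfer_function",
    "adtf_normalize",
    "integrate_adtf",
    "phase_randomize",
    "surrogate_null",
    "net_flow",
    "time_varying_network",
]


@dataclass
class MVAARFit:
    """Time-resolved VAR coefficients w(k, t) and one-step prediction residuals.

    ``coeffs[t, k, i, j]`` couples node j at lag k+1 into node i when predicting
    time t.  Entries before the model order p repeat the first defined estimate.
    """

    coeffs: np.ndarray  # (T, p, n, n)
    order: int
    uc: float
    residuals: np.ndarray  # (T, n); zeros before t = p

    @property
    def n_nodes(self) -> int:
        return self.coeffs.shape[2]

    @property
    def n_times(self) -> int:
        return self.coeffs.shape[0]

    @property
    def burn_in(self) -> int:
        """First index with a usable estimate: max(50, 5·p)."""
        return max(50, 5 * self.order)


@dataclass
class TVNetwork:
    """Normalized and band-integrated ADTF with optional surrogate significance."""

    adtf: np.ndarray  # (n_times_sel, n_freqs, n, n) — ι²(f, t)
    integrated: np.ndarray  # (n_times_sel, n, n) — ϑ²(t)
    freqs: np.ndarray
    times: np.ndarray  # sample indices into the original series
    node_names: list[str]
    null_thresholds: np.ndarray | None = None  # (n, n) 95th-percentile levels
    significant: np.ndarray | None = None  # (n_times_sel, n, n) bool


@dataclass
class SurrogateNull:
    """Empirical null for the integrated ADTF from phase-randomized surrogates."""

    samples: np.ndarray  # (n_surrogates, n_times_sel, n, n)
    thresholds: np.ndarray  # (n, n) — pooled across time by default
    percentile: float
    pooled: bool


def region_time_series(S: np.ndarray, regions) -> np.ndarray:
    """Average dipole waveforms within each region: nodes × time.

    ``regions`` is a sequence of non-empty, pairwise-disjoint dipole index sets.
    """
    S = np.asarray(S, float)
    seen: set[int] = set()
    rows = []
    for reg in regions:
        idx = np.asarray(reg, int)
        if idx.size == 0:
            raise ValueError("empty region")
        if seen.intersection(idx.tolist()):
            raise ValueError("regions must be disjoint")
        seen.update(idx.tolist())
        rows.append(S[idx].mean(axis=0))
    return np.stack(rows)


def fit_mvaar_kalman(
    X: np.ndarray,
    p: int,
    uc: float = 1e-3,
    p0: float = 100.0,
) -> MVAARFit:
    """Track time-varying VAR coefficients with a Kalman/RLS recursion.

    The coefficient matrix W (n × n·p) is the state; at each step the regressor
    h(t) = [X(t−1); …; X(t−p)] updates all rows through a shared gain with forgetting
    factor 1 − uc, so the effective memory is ≈ 1/uc samples.  Deterministic.

    ``X`` may be (n, T) or batched (B, n, T); batching shares the per-step Python
    overhead across, e.g., surrogate realizations.

    Returns a fit whose first ``burn_in`` time points should not be summarized.
    """
    X = np.asarray(X, float)
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite values")
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    B, n, T = X.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    if T < 10 * p * n:
        raise ValueError(f"series too short: need T >= 10·p·n = {10 * p * n}")
    if not 0 < uc < 1:
        raise ValueError("uc must lie in (0, 1)")
    lam = 1.0 - uc
    d = n * p
    W = np.zeros((B, n, d))
    P = np.broadcast_to(np.eye(d) * p0, (B, d, d)).copy()
    coeffs = np.zeros((B, T, p, n, n))
    resid = np.zeros((B, T, n))
    for t in range(p, T):
        # regressor: lags 1..p stacked lag-major → (B, d), matching W's lag blocks
        h = X[:, :, t - p : t][:, :, ::-1].transpose(0, 2, 1).reshape(B, d)
        yhat = np.einsum("bnd,bd->bn", W, h)
        err = X[:, :, t] - yhat
        Ph = np.einsum("bde,be->bd", P, h)
        denom = lam + np.einsum("bd,bd->b", h, Ph)
        K = Ph / denom[:, None]
        W = W + err[:, :, None] * K[:, None, :]
        P = (P - K[:, :, None] * Ph[:, None, :]) / lam
        resid[:, t] = err
        coeffs[:, t] = W.reshape(B, n, p, n).transpose(0, 2, 1, 3)
    coeffs[:, :p] = coeffs[:, p : p + 1]
    if squeeze:
        return MVAARFit(coeffs=coeffs[0], order=p, uc=uc, residuals=resid[0])
    return [
        MVAARFit(coeffs=coeffs[b], order=p, uc=uc, residuals=resid[b])
        for b in range(B)
    ]


def select_order_sbc(X: np.ndarray, p_max: int) -> int:
    """VAR model order minimizing the Schwarz Bayesian criterion, clamped to ≥ 1.

    Uses stationary least-squares fits over orders 0..p_max (statsmodels); white
    noise therefore yields the smallest allowed order, 1.
    """
    from statsmodels.tsa.vector_ar.var_model import VAR

    X = np.asarray(X, float)
    n, T = X.shape
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if T < (p_max + 1) * n + p_max + 10:
        raise ValueError(f"series of length {T} too short for p_max={p_max}")
    sel = VAR(X.T).select_order(maxlags=p_max)
    return int(max(1, min(p_max, sel.bic)))


def _coeff_fourier(coeffs: np.ndarray, freqs: np.ndarray, sfreq: float) -> np.ndarray:
    """A(f, t) = I − Σ_k w_k(t) e^{−j2πf(k+1)/sfreq} for a (T, p, n, n) tensor."""
    T, p, n, _ = coeffs.shape
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / sfreq)  # (F, p)
    Af = -np.einsum("fk,tkij->tfij", phase, coeffs)
    Af += np.eye(n)
    return Af


def transfer_function(
    fit: MVAARFit,
    freqs: np.ndarray,
    sfreq: float,
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """H(f, t) = A(f, t)⁻¹ on a frequency grid, at the requested time indices.

    Returns ``(H, times)`` with H of shape (n_times, n_freqs, n, n).  Raises on a
    singular coefficient spectrum, naming the offending (frequency, time) pair.
    """
    freqs = np.asarray(freqs, float)
    if times is None:
        times = np.arange(fit.burn_in, fit.n_times)
    times = np.asarray(times, int)
    Af = _coeff_fourier(fit.coeffs[times], freqs, sfreq)
    dets = np.abs(np.linalg.det(Af))
    if (dets < 1e-12).any():
        t_i, f_i = np.argwhere(dets < 1e-12)[0]
        raise np.linalg.LinAlgError(
            f"singular A(f,t) at f={freqs[f_i]} Hz, t={times[t_i]}"
        )
    return np.linalg.inv(Af), times


def adtf_normalize(H: np.ndarray) -> np.ndarray:
    """Normalized ADTF ι²_ij = |H_ij|² / Σ_k |H_ik|²; receiver rows sum to 1."""
    P = np.abs(np.asarray(H)) ** 2
    denom = P.sum(axis=-1, keepdims=True)
    if (denom == 0).any():
        raise ValueError("zero-power receiver row: normalization undefined")
    return P / denom


def integrate_adtf(
    adtf: np.ndarray, freqs: np.ndarray, f1: float = 4.0, f2: float = 30.0
) -> np.ndarray:
    """Integrated ADTF ϑ²_ij(t): mean of ι² over frequency bins within [f1, f2]."""
    freqs = np.asarray(freqs, float)
    mask = (freqs >= f1) & (freqs <= f2)
    if not mask.any():
        raise ValueError(f"no frequency bins inside [{f1}, {f2}] Hz")
    return np.asarray(adtf)[..., mask, :, :].mean(axis=-3)


def net_flow(theta_ij: np.ndarray, theta_ji: np.ndarray) -> np.ndarray:
    """Pure (net) information flow: ϑ²_ij − ϑ²_ji.

    With ι²_ij quantifying j→i, a positive result means net flow j→i.
    """
    return np.asarray(theta_ij) - np.asarray(theta_ji)


def phase_randomize(X: np.ndarray, n_surrogates: int, seed: int) -> np.ndarray:
    """Phase-randomized surrogates, independently per node: (B, n, T).

    Each node's Fourier amplitude spectrum is preserved exactly; phases of all
    non-DC (and non-Nyquist) bins are redrawn uniformly with Hermitian symmetry, so
    the surrogates are real with unchanged autospectra but destroyed cross-node
    phase relations.
    """
    X = np.asarray(X, float)
    n, T = X.shape
    rng = np.random.default_rng(seed)
    F = np.fft.rfft(X, axis=-1)
    nf = F.shape[-1]
    phases = rng.uniform(0, 2 * np.pi, size=(n_surrogates, n, nf))
    phases[..., 0] = 0.0
    if T % 2 == 0:
        phases[..., -1] = 0.0
    Fs = np.abs(F)[None] * np.exp(1j * (np.angle(F)[None] + phases))
    return np.fft.irfft(Fs, n=T, axis=-1)


def surrogate_null(
    X: np.ndarray,
    p: int,
    sfreq: float,
    uc: float = 1e-3,
    n_surrogates: int = 200,
    seed: int = 0,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] = (4.0, 30.0),
    time_step: int = 5,
    percentile: float = 95.0,
    pooled: bool = True,
) -> tuple[SurrogateNull, np.ndarray, np.ndarray]:
    """Empirical no-coupling null for the integrated ADTF.

    Runs the full fit → H → ι² → ϑ² pipeline on ``n_surrogates`` phase-randomized
    copies of ``X`` (batched), evaluating every ``time_step``-th post-burn-in time
    point.  The per-edge threshold is the ``percentile`` of the null, pooled across
    retained time points by default (per-time thresholds when ``pooled=False``).

    Returns ``(null, theta2_actual, times)`` where ``theta2_actual`` is the observed
    integrated ADTF on the same time grid.
    """
    X = np.asarray(X, float)
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    n, T = X.shape
    if freqs is None:
        freqs = np.arange(1.0, sfreq / 2)
    fit = fit_mvaar_kalman(X, p=p, uc=uc)
    times = np.arange(fit.burn_in, T, time_step)
    H, _ = transfer_function(fit, freqs, sfreq, times=times)
    theta2 = integrate_adtf(adtf_normalize(H), freqs, *band)

    surr = phase_randomize(X, n_surrogates, seed=seed)
    samples = np.empty((n_surrogates, times.size, n, n))
    fits = fit_mvaar_kalman(surr, p=p, uc=uc)
    for b in range(n_surrogates):
        Hb, _ = transfer_function(fits[b], freqs, sfreq, times=times)
        samples[b] = integrate_adtf(adtf_normalize(Hb), freqs, *band)
    if pooled:
        thresholds = np.percentile(samples.reshape(-1, n, n), percentile, axis=0)
    else:
        thresholds = np.percentile(samples, percentile, axis=0)
    null = SurrogateNull(
        samples=samples, thresholds=thresholds, percentile=percentile, pooled=pooled
    )
    return null, theta2, times


def time_varying_network(
    X: np.ndarray,
    sfreq: float,
    p: int | None = None,
    p_max: int = 10,
    uc: float = 1e-3,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] = (4.0, 30.0),
    n_surrogates: int = 200,
    seed: int = 0,
    time_step: int = 5,
    node_names: list[str] | None = None,
) -> TVNetwork:
    """End-to-end network analysis of node series X (nodes × time).

    Order selection (SBC) when ``p`` is None, Kalman MVAAR fit, transfer function on
    a 1-Hz grid, ADTF normalization, band integration, and (when ``n_surrogates`` >
    0) surrogate significance of each directed edge.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if p is None:
        p = select_order_sbc(X, p_max)
    if freqs is None:
        freqs = np.arange(1.0, sfreq / 2)
    if node_names is None:
        node_names = [f"node{i}" for i in range(n)]
    if n_surrogates > 0:
        null, theta2, times = surrogate_null(
            X, p=p, sfreq=sfreq, uc=uc, n_surrogates=n_surrogates, seed=seed,
            freqs=freqs, band=band, time_step=time_step,
        )
        fit = fit_mvaar_kalman(X, p=p, uc=uc)
        H, _ = transfer_function(fit, freqs, sfreq, times=times)
        adtf = adtf_normalize(H)
        sig = theta2 > null.thresholds
        for i in range(n):  # self-loops are not edges
            sig[:, i, i] = False
        return TVNetwork(
            adtf=adtf, integrated=theta2, freqs=freqs, times=times,
            node_names=node_names, null_thresholds=null.thresholds, significant=sig,
        )
    fit = fit_mvaar_kalman(X, p=p, uc=uc)
    times = np.arange(fit.burn_in, X.shape[1], time_step)
    H, _ = transfer_function(fit, freqs, sfreq, times=times)
    adtf = adtf_normalize(H)
    theta2 = integrate_adtf(adtf, freqs, *band)
    return TVNetwork(
        adtf=adtf, integrated=theta2, freqs=freqs, times=times, node_names=node_names
    )
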