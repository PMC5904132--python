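"""Synthetic scalp-EEG generator with known ground truth.

Stands in for unavailable recordings: two trial classes ("error" vs "correct") whose
active cortical dipoles differ only in how their power is split across the theta,
alpha and beta rhythms — hence in rhythm entropy — mixed to the scalp through a known
linear leadfield with additive white sensor noise.  A separate stable-VAR simulator
provides directionally coupled node series for the connectivity stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preproc import BANDS, BAND_ORDER, EpochSet, _sos_filter

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_leadfield",
    "simulate_band_source",
    "simulate_mvar_nodes",
    "simulate_dataset",
    "analytic_entropy",
]


def analytic_entropy(props) -> float:
    """Shannon entropy (bits) of a proportion vector, with 0·log2(0) := 0."""
    p = np.asarray(props, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass(frozen=True)
class RTModel:
    """Truncated-normal reaction-time model (ms); error responses are slower."""

    error_mean: float = 800.0
    error_sd: float = 120.0
    correct_mean: float = 650.0
    correct_sd: float = 100.0
    floor: float = 100.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a single subject's session: 32 channels, 200 cortical dipoles of
    which three small clusters are active, 20 trials per class of 700 ms at 250 Hz,
    theta-dominant power in error trials ((0.8, 0.1, 0.1)) versus a uniform rhythm
    split in correct trials, and scalp SNR of 10 (signal power / sensor-noise power).
    """

    n_channels: int = 32
    n_dipoles: int = 200
    sfreq: float = 250.0
    epoch_len: float = 0.7
    n_trials_per_class: int = 20
    active_dipoles: tuple[int, ...] = (20, 21, 22, 90, 91, 150, 151, 152)
    band_props_error: tuple[float, float, float] = (0.8, 0.1, 0.1)
    band_props_correct: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    sensor_snr: float = 10.0
    source_power: float = 1.0  # mean-square amplitude of an active dipole, µV²
    background_amp_frac: float = 0.1  # inactive-dipole amplitude relative to active
    rt_model: RTModel = field(default_factory=RTModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("band_props_error", "band_props_correct"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,) or (p < 0).any():
                raise ValueError(f"{name} must be a nonnegative 3-vector")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 (got {p.sum()!r})")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.sfreq <= 2 * BANDS["beta"][1]:
            raise ValueError("sfreq must put the beta band (30 Hz) below Nyquist")
        if self.epoch_len * self.sfreq < 2 * self.sfreq / BANDS["theta"][0]:
            raise ValueError("epoch too short: need at least two theta cycles")
        if max(self.active_dipoles) >= self.n_dipoles:
            raise ValueError("active dipole index out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_len * self.sfreq))


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream recovery checks."""

    active_dipoles: tuple[int, ...]
    class_entropy: dict[str, float]  # analytic −Σ p log2 p, bits, per class
    rt: np.ndarray  # per-trial, ms
    coupling_graph: np.ndarray | None = None  # directed adjacency for node sims


def make_leadfield(
    n_channels: int, n_dipoles: int, seed: int, smooth_sigma: float = 0.8
) -> np.ndarray:
    """Random smooth mixing matrix standing in for a BEM leadfield.

    Rows are spatially correlated (Gaussian smoothing of a white draw across the
    channel axis, emulating volume conduction's spatial blur) and columns are scaled
    to unit norm.  The default smoothing is mild so the matrix keeps a realistic
    effective rank — a genuine electrode montage is not rank-deficient, only
    correlated.  Guaranteed full row rank; deterministic for a fixed seed.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if n_dipoles < n_channels:
        raise ValueError("need n_dipoles >= n_channels")
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    for _ in range(10):
        A = rng.standard_normal((n_channels, n_dipoles))
        A = gaussian_filter1d(A, sigma=smooth_sigma, axis=0, mode="nearest")
        A /= np.linalg.norm(A, axis=0, keepdims=True)
        if np.linalg.matrix_rank(A) == n_channels:
            return A
    raise RuntimeError("could not draw a full-row-rank leadfield in 10 attempts")


def simulate_band_source(
    props,
    total_power: float,
    n_samples: int,
    sfreq: float,
    seed,
) -> np.ndarray:
    """One dipole's time course: three band-limited noise components with exact powers.

    Each component is white noise passed through a zero-phase band-pass and rescaled
    so its mean-square power equals ``props[i] * total_power`` exactly; filter leakage
    outside the band edges is the only deviation the spectrum then shows.
    """
    p = np.asarray(props, dtype=float)
    if p.shape != (3,) or (p < 0).any():
        raise ValueError("props must be a nonnegative 3-vector")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("props must sum to 1")
    if n_samples < 2 * sfreq / BANDS["theta"][0]:
        raise ValueError("n_samples too short for two theta cycles")
    rng = np.random.default_rng(seed)
    pad = int(sfreq)  # one-second guard band against filter transients
    out = np.zeros(n_samples)
    for i, name in enumerate(BAND_ORDER):
        if p[i] == 0:
            continue
        sos = _sos_filter(*BANDS[name], sfreq)
        x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples + 2 * pad))[pad:-pad]
        ms = np.mean(x**2)
        out += x * np.sqrt(p[i] * total_power / ms)
    return out


def _companion_radius(coeffs: np.ndarray) -> float:
    p, n, _ = coeffs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


def simulate_mvar_nodes(
    coeffs: np.ndarray,
    n_samples: int,
    noise_sd: float = 1.0,
    seed: int = 0,
    burn_in: int = 200,
) -> np.ndarray:
    """Simulate a stationary VAR(p) process; returns nodes × samples.

    ``coeffs`` has shape (p, n, n): ``coeffs[k][i, j]`` couples node j at lag k+1 into
    node i, so nonzero off-diagonal entries are the ground-truth directed edges.
    Rejects unstable systems (companion-matrix spectral radius >= 1).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
        raise ValueError("coeffs must have shape (p, n, n)")
    radius = _companion_radius(coeffs)
    if radius >= 1:
        raise ValueError(f"unstable VAR: companion spectral radius = {radius:.4f}")
    p, n, _ = coeffs.shape
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in + p
    X = np.zeros((n, total))
    eps = rng.normal(scale=noise_sd, size=(n, total))
    for t in range(p, total):
        acc = eps[:, t].copy()
        for k in range(p):
            acc += coeffs[k] @ X[:, t - k - 1]
        X[:, t] = acc
    return X[:, -n_samples:]


def simulate_dataset(config: SimConfig) -> tuple[EpochSet, GroundTruth]:
    """Generate one epoched dataset plus its ground truth.

    Active dipoles carry class-specific band-power proportions; inactive dipoles carry
    low-amplitude broadband (4–30 Hz) background.  Scalp data are
    ``leadfield @ sources`` plus white sensor noise scaled per trial so that the
    signal-power / noise-power ratio equals ``sensor_snr``.  Trial order is shuffled;
    labels stay balanced.
    """
    rng = np.random.default_rng(config.seed)
    seed_for = lambda: int(rng.integers(2**31))  # noqa: E731

    A = make_leadfield(config.n_channels, config.n_dipoles, seed=seed_for())
    n_tr = 2 * config.n_trials_per_class
    n_samp = config.n_samples
    labels = np.array(
        ["error"] * config.n_trials_per_class + ["correct"] * config.n_trials_per_class
    )
    order = rng.permutation(n_tr)
    labels = labels[order]

    props = {
        "error": np.asarray(config.band_props_error),
        "correct": np.asarray(config.band_props_correct),
    }
    active = np.asarray(config.active_dipoles, dtype=int)
    inactive = np.setdiff1d(np.arange(config.n_dipoles), active)
    bg_power = (config.background_amp_frac**2) * config.source_power
    bg_sos = _sos_filter(BANDS["theta"][0], BANDS["beta"][1], config.sfreq)
    pad = int(config.sfreq)

    data = np.empty((n_tr, config.n_channels, n_samp))
    for t in range(n_tr):
        S = np.zeros((config.n_dipoles, n_samp))
        for d in active:
            S[d] = simulate_band_source(
                props[labels[t]], config.source_power, n_samp, config.sfreq, seed_for()
            )
        bg_rng = np.random.default_rng(seed_for())
        bg = signal.sosfiltfilt(
            bg_sos, bg_rng.standard_normal((inactive.size, n_samp + 2 * pad)), axis=-1
        )[:, pad:-pad]
        bg *= np.sqrt(bg_power / np.mean(bg**2, axis=1, keepdims=True))
        S[inactive] = bg
        x = A @ S
        sig_power = np.mean(x**2)
        noise_rng = np.random.default_rng(seed_for())
        x = x + noise_rng.normal(
            scale=np.sqrt(sig_power / config.sensor_snr), size=x.shape
        )
        data[t] = x

    rtm = config.rt_model
    rt = np.empty(n_tr)
    rt_rng = np.random.default_rng(seed_for())
    for t in range(n_tr):
        mu, sd = (
            (rtm.error_mean, rtm.error_sd)
            if labels[t] == "error"
            else (rtm.correct_mean, rtm.correct_sd)
        )
        val = rt_rng.normal(mu, sd)
        while val < rtm.floor:
            val = rt_rng.normal(mu, sd)
        rt[t] = val

    epochs = EpochSet(
        data=data,
        sfreq=config.sfreq,
        labels=labels,
        rt=rt,
        window=(0.0, config.epoch_len),
    )
    truth = GroundTruth(
        active_dipoles=tuple(active.tolist()),
        class_entropy={
            "error": analytic_entropy(config.band_props_error),
            "correct": analytic_entropy(config.band_props_correct),
        },
        rt=rt.copy(),
    )
    return epochs, truth
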