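"""Rhythm entropy: Shannon entropy of the theta/alpha/beta band-power split.

For each trial and dipole the power of the band-filtered source signal is
Power_b = Σ_t S_b(t)², the three powers are normalized to proportions
P_b = Power_b / Σ Power_b, and the feature is iEn = −Σ P_b log2 P_b (bits).
A uniform split gives the maximum log2(3) ≈ 1.585; a single dominant rhythm gives 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preproc import BAND_ORDER

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateTrialError",
    "FeatureTable",
    "band_power",
    "normalize_powers",
    "rhythm_entropy",
    "features_per_dataset",
]

MAX_ENTROPY = float(np.log2(3))


class DegenerateTrialError(ValueError):
    """All three band powers are zero — no proportion vector exists."""


@dataclass
class FeatureTable:
    """Per-trial, per-dipole rhythm-entropy features with audit information."""

    values: np.ndarray  # trials × dipoles, bits
    labels: np.ndarray  # per-trial class
    band_powers: np.ndarray  # trials × dipoles × 3 (theta, alpha, beta)
    rt: np.ndarray | None = None  # per-trial reaction time, ms
    kept_trials: np.ndarray | None = None  # original indices of surviving trials

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.values.shape[1]

    def subset_trials(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        kept = self.kept_trials[idx] if self.kept_trials is not None else None
        return FeatureTable(
            values=self.values[idx],
            labels=self.labels[idx],
            band_powers=self.band_powers[idx],
            rt=None if self.rt is None else self.rt[idx],
            kept_trials=kept,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long-format view: one row per (trial, dipole)."""
        t, d = np.meshgrid(
            np.arange(self.n_trials), np.arange(self.n_dipoles), indexing="ij"
        )
        frame = {
            "trial": t.ravel(),
            "dipole": d.ravel(),
            "entropy": self.values.ravel(),
            "label": np.repeat(self.labels, self.n_dipoles),
        }
        if self.rt is not None:
            frame["rt"] = np.repeat(self.rt, self.n_dipoles)
        return pd.DataFrame(frame)


def band_power(segment) -> float:
    """Sum of squared amplitudes over the trial window."""
    x = np.asarray(segment, float)
    if x.size == 0:
        raise ValueError("empty segment has no power")
    return float(np.sum(x**2))


def normalize_powers(p_theta: float, p_alpha: float, p_beta: float) -> np.ndarray:
    """Normalize the three band powers to proportions summing to 1."""
    p = np.asarray([p_theta, p_alpha, p_beta], float)
    if (p < 0).any():
        raise ValueError("band powers must be nonnegative")
    total = p.sum()
    if total == 0:
        raise DegenerateTrialError("all three band powers are zero")
    return p / total


def rhythm_entropy(P) -> float:
    """iEn = −Σ P_i log2 P_i in bits, with 0·log2(0) := 0."""
    p = np.asarray(P, float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def features_per_dataset(
    band_sources: dict[str, np.ndarray],
    labels,
    rt=None,
) -> FeatureTable:
    """Assemble the trials × dipoles rhythm-entropy matrix from per-band sources.

    Parameters
    ----------
    band_sources : dict
        ``{"theta"|"alpha"|"beta": ndarray (trials, dipoles, samples)}`` — all three
        bands required, same shape.
    labels, rt : per-trial metadata aligned with the trial axis.

    Trials containing any dipole with zero total band power are degenerate (no
    proportion vector exists); they are dropped and logged, and ``kept_trials``
    records the surviving original indices.
    """
    missing = [b for b in BAND_ORDER if b not in band_sources]
    if missing:
        raise ValueError(f"missing band(s): {missing}")
    arrs = [np.asarray(band_sources[b], float) for b in BAND_ORDER]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("band arrays must share one (trials, dipoles, samples) shape")
    powers = np.stack([np.sum(a**2, axis=-1) for a in arrs], axis=-1)
    total = powers.sum(axis=-1)

    labels = np.asarray(labels)
    rt = None if rt is None else np.asarray(rt, float)
    ok = ~(total == 0).any(axis=1)
    if not ok.all():
        logger.warning(
            "dropping %d degenerate trial(s) with all-zero band power: %s",
            (~ok).sum(), np.flatnonzero(~ok).tolist(),
        )
    powers = powers[ok]
    total = total[ok]

    with np.errstate(divide="ignore", invalid="ignore"):
        P = powers / total[..., None]
        logs = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
    values = -(P * logs).sum(axis=-1)
    return FeatureTable(
        values=values,
        labels=labels[ok],
        band_powers=powers,
        rt=None if rt is None else rt[ok],
        kept_trials=np.flatnonzero(ok),
    )
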