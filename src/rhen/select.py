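"""Discriminative-dipole selection by R² and back-projection to dipole space.

R² is the squared standardized class-mean difference
(mean(X₊) − mean(X₋))² / (4 σ²), with σ the population SD of the pooled feature
values; at equal class sizes this equals the squared point-biserial correlation
between the feature and the class tag.  Dipoles within a fraction of the maximum R²
(default 0.6) are retained; a sweep over fractions 0.1…1.0 picks the fraction
maximizing LOOCV accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import loocv_with_selection
from .entropy import FeatureTable

__all__ = [
    "R2Map",
    "r_square",
    "r_square_map",
    "select_dipoles",
    "back_project",
    "compute_r2_map",
    "threshold_sweep",
]

POS_LABEL = "error"


@dataclass
class R2Map:
    """Per-dipole discriminability with threshold, selection, and back-projection."""

    r2: np.ndarray
    threshold_frac: float
    selected: np.ndarray  # dipole indices
    projected: np.ndarray  # full-dipole-space map (zeros off the selection)


def r_square(x_pos, x_neg) -> float:
    """Squared standardized mean difference between the two classes' features.

    Constant pooled features yield 0 with a warning rather than a division error.
    """
    x_pos = np.asarray(x_pos, float)
    x_neg = np.asarray(x_neg, float)
    if x_pos.size < 2 or x_neg.size < 2:
        raise ValueError("each class needs at least 2 samples")
    pooled = np.concatenate([x_pos, x_neg])
    var = pooled.var(ddof=0)
    if var == 0:
        warnings.warn("constant feature: R² defined as 0", RuntimeWarning)
        return 0.0
    return float((x_pos.mean() - x_neg.mean()) ** 2 / (4.0 * var))


def r_square_map(values: np.ndarray, labels, pos_label: str = POS_LABEL) -> np.ndarray:
    """Vectorized per-column R² of a trials × dipoles feature matrix."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    pos = labels == pos_label
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    diff = values[pos].mean(axis=0) - values[~pos].mean(axis=0)
    var = values.var(axis=0, ddof=0)
    out = np.zeros(values.shape[1])
    nz = var > 0
    out[nz] = diff[nz] ** 2 / (4.0 * var[nz])
    return out


def select_dipoles(r2: np.ndarray, threshold_frac: float = 0.6) -> np.ndarray:
    """Indices of dipoles with R² ≥ threshold_frac · max(R²); never empty."""
    r2 = np.asarray(r2, float)
    return np.flatnonzero(r2 >= threshold_frac * r2.max())


def back_project(r2_selected, selected_idx, n_dipoles: int) -> np.ndarray:
    """Place selected-space R² values back into the full dipole space (identity U).

    Unselected dipoles get 0, so the map's support marks the discriminative regions.
    """
    r2_selected = np.asarray(r2_selected, float)
    selected_idx = np.asarray(selected_idx, int)
    if selected_idx.size and (
        selected_idx.min() < 0 or selected_idx.max() >= n_dipoles
    ):
        raise IndexError("selected dipole index out of range")
    D = np.zeros(n_dipoles)
    D[selected_idx] = r2_selected
    return D


def compute_r2_map(features: FeatureTable, threshold_frac: float = 0.6) -> R2Map:
    """Full R² analysis of a feature table: map, selection, back-projection."""
    r2 = r_square_map(features.values, features.labels)
    sel = select_dipoles(r2, threshold_frac)
    return R2Map(
        r2=r2,
        threshold_frac=threshold_frac,
        selected=sel,
        projected=back_project(r2[sel], sel, features.n_dipoles),
    )


def threshold_sweep(
    features: FeatureTable,
    fracs=None,
    mode: str = "per-fold",
    seed: int = 0,
    **loocv_kwargs,
) -> tuple[pd.DataFrame, float]:
    """LOOCV accuracy at each R² threshold fraction; returns (table, best fraction).

    Fractions default to 0.1, 0.2, …, 1.0.  Ties between fractions go to the smallest
    one (fewest assumptions about how far below the maximum R² signal extends).
    """
    if fracs is None:
        fracs = np.round(np.arange(0.1, 1.0 + 1e-9, 0.1), 10)
    rows = []
    r2_all = r_square_map(features.values, features.labels)
    for frac in fracs:
        res = loocv_with_selection(
            features, threshold_frac=float(frac), mode=mode, seed=seed, **loocv_kwargs
        )
        rows.append(
            {
                "frac": float(frac),
                "accuracy": res.ca,
                "auc": res.auc,
                "n_selected": int(select_dipoles(r2_all, float(frac)).size),
            }
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["accuracy"].idxmax(), "frac"]  # idxmax → first (smallest)
    return table, float(best)
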