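"""Weighted-minimum-norm source estimation.

The linear inverse operator is W = R Aᵀ (A R Aᵀ + λ²C)⁻¹, with A the leadfield,
R and C the source and sensor-noise covariances, and λ² = trace(ARAᵀ)/(trace(C)·SNR²).
With R = C = I this is the Tikhonov-regularized minimum-norm solution; an optional
depth weighting sets R = diag(‖a_j‖⁻²) to counteract the bias toward superficial
(large-gain) dipoles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InverseModel",
    "SourceTrial",
    "compute_lambda2",
    "compute_inverse_operator",
    "apply_inverse",
]

_COND_LIMIT = 1e12


@dataclass
class InverseModel:
    """A fitted linear inverse operator and the quantities that define it."""

    A: np.ndarray  # channels × dipoles gain matrix
    R: np.ndarray  # dipoles × dipoles source covariance
    C: np.ndarray  # channels × channels noise covariance
    snr: float
    lambda2: float
    W: np.ndarray  # dipoles × channels inverse operator


@dataclass
class SourceTrial:
    """Cortical activity of one trial in one rhythm band (dipoles × samples)."""

    S: np.ndarray
    band: str
    trial_id: int


def compute_lambda2(A, R, C, snr: float = 5.0) -> float:
    """Regularization parameter λ² = trace(A R Aᵀ) / (trace(C) · snr²).

    The fixed default snr=5 is the conventional value for evoked-response data.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    A = np.asarray(A, float)
    R = np.asarray(R, float)
    C = np.asarray(C, float)
    tC = np.trace(C)
    if tC <= 0:
        raise ValueError("trace(C) must be positive")
    return float(np.trace(A @ R @ A.T) / (tC * snr**2))


def _default_R(A: np.ndarray, depth_weighting: bool) -> np.ndarray:
    if not depth_weighting:
        return np.eye(A.shape[1])
    norms = np.linalg.norm(A, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    return np.diag(1.0 / norms**2)


def compute_inverse_operator(
    A,
    R=None,
    C=None,
    snr: float = 5.0,
    lambda2: float | None = None,
    depth_weighting: bool = False,
) -> InverseModel:
    """Build W = R Aᵀ (A R Aᵀ + λ²C)⁻¹ via a numerically stable solve.

    ``R`` and ``C`` default to identities (optionally depth-weighted R); ``lambda2``
    overrides the SNR-derived value, ``lambda2=0`` giving the unregularized limit.

    Raises
    ------
    numpy.linalg.LinAlgError
        If A R Aᵀ + λ²C is singular or numerically unusable; the message carries the
        condition number.
    """
    A = np.asarray(A, float)
    if A.ndim != 2:
        raise ValueError("A must be a 2-D gain matrix")
    R = _default_R(A, depth_weighting) if R is None else np.asarray(R, float)
    C = np.eye(A.shape[0]) if C is None else np.asarray(C, float)
    if lambda2 is None:
        lambda2 = compute_lambda2(A, R, C, snr=snr)
    M = A @ R @ A.T + lambda2 * C
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"A R Aᵀ + λ²C is numerically singular (condition number {cond:.3g})"
        )
    # W = R Aᵀ M⁻¹  ⇔  Wᵀ = M⁻¹ A R (M, R symmetric)
    W = np.linalg.solve(M, A @ R).T
    return InverseModel(A=A, R=R, C=C, snr=snr, lambda2=float(lambda2), W=W)


def apply_inverse(model: InverseModel, data: np.ndarray) -> np.ndarray:
    """Map scalp data to dipole space: S = W x.

    ``data`` may be (channels, samples) or (trials, channels, samples); the dipole
    axis replaces the channel axis in the output.
    """
    data = np.asarray(data, float)
    n_ch = model.W.shape[1]
    if data.ndim == 2:
        if data.shape[0] != n_ch:
            raise ValueError(f"expected {n_ch} channels, got {data.shape[0]}")
        return model.W @ data
    if data.ndim == 3:
        if data.shape[1] != n_ch:
            raise ValueError(f"expected {n_ch} channels, got {data.shape[1]}")
        return np.einsum("dc,tcs->tds", model.W, data)
    raise ValueError("data must be 2-D or 3-D")
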