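"""Association statistics: Pearson correlation of reaction time with rhythm entropy
or with degree-adjusted connectivity, and paired comparisons of entropy between the
error and correct conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .network import TVNetwork

__all__ = [
    "AssociationResult",
    "pearson_rt_entropy",
    "paired_entropy_test",
    "degree_adjust",
    "weighted_degree",
]


@dataclass
class AssociationResult:
    """One association test: effect size, p-value, and sample size."""

    n: int
    p: float
    r: float | None = None  # Pearson coefficient
    t: float | None = None  # paired-t statistic
    d: float | None = None  # Cohen's d for the paired contrast


def pearson_rt_entropy(rt, en) -> AssociationResult:
    """Pearson correlation (two-sided p) between reaction times and entropy values."""
    rt = np.asarray(rt, float)
    en = np.asarray(en, float)
    if rt.shape != en.shape or rt.ndim != 1:
        raise ValueError("rt and en must be 1-D and equally long")
    if rt.size < 3:
        raise ValueError("correlation needs n >= 3")
    if rt.std() == 0 or en.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(rt, en)
    return AssociationResult(n=rt.size, p=float(res.pvalue), r=float(res.statistic))


def paired_entropy_test(en_error, en_correct) -> AssociationResult:
    """Paired t-test of per-subject entropy between conditions, with Cohen's d.

    d = mean(diff) / sd(diff) (sample SD).  Zero-variance differences are degenerate
    and rejected rather than reported as infinite effects.
    """
    a = np.asarray(en_error, float)
    b = np.asarray(en_correct, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equally long")
    if a.size < 2:
        raise ValueError("paired test needs n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return AssociationResult(n=a.size, p=1.0, t=0.0, d=0.0)
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = sps.ttest_rel(a, b)
    return AssociationResult(
        n=a.size,
        p=float(res.pvalue),
        t=float(res.statistic),
        d=float(diff.mean() / sd),
    )


def weighted_degree(
    integrated: np.ndarray, node: int, mode: str = "total"
) -> np.ndarray:
    """Weighted degree of ``node``: summed incident edge strengths, no self-terms.

    ``integrated`` is (..., n, n) with entry [i, j] the flow j→i.  ``mode`` selects
    in-strength (Σ_j≠node ϑ²[node, j]), out-strength (Σ_j≠node ϑ²[j, node]) or their
    sum (default).
    """
    W = np.asarray(integrated, float)
    n = W.shape[-1]
    mask = np.arange(n) != node
    instr = W[..., node, :][..., mask].sum(axis=-1)
    outstr = W[..., :, node][..., mask].sum(axis=-1)
    if mode == "in":
        return instr
    if mode == "out":
        return outstr
    if mode == "total":
        return instr + outstr
    raise ValueError(f"unknown degree mode: {mode!r}")


def degree_adjust(
    edge_value,
    network: TVNetwork | np.ndarray,
    node: int,
    time_index: int | None = None,
    mode: str = "total",
):
    """Divide an edge's integrated-ADTF value by the node's weighted degree.

    Makes edge strengths comparable across networks of different overall density
    (scaling every edge by a constant leaves the adjusted value unchanged).
    """
    W = network.integrated if isinstance(network, TVNetwork) else np.asarray(network)
    if time_index is not None:
        W = W[time_index]
    deg = weighted_degree(W, node, mode=mode)
    if np.any(deg == 0):
        raise ValueError("zero weighted degree: adjustment undefined")
    return np.asarray(edge_value, float) / deg
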