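"""Comparison statistics for codon-usage indices.

Spearman rank correlations between gene-level indices, Williams' test for
comparing two dependent correlations that share one variable (e.g. rho(tAI,
CAI) vs rho(stAI, CAI) with CAI shared), and repeated random-subsample
correlation distributions used to rule out reference-set-driven inflation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


def spearman(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class WilliamsResult:
    t: float
    p: float
    df: int


def williams_test(r12: float, r13: float, r23: float, n: int) -> WilliamsResult:
    """Williams' t for H0: rho12 = rho13 with variable 1 shared, df = n - 3.

        t = (r12 - r13) * sqrt( (n-1)(1+r23) /
              ( 2K(n-1)/(n-3) + rbar^2 (1-r23)^3 ) )

    with K = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23 (the determinant of
    the 3x3 correlation matrix) and rbar = (r12 + r13)/2.  Two-sided p from
    the t distribution with n - 3 degrees of freedom.
    """
    if n < 4:
        raise ValueError("Williams' test requires n >= 4 (df = n - 3 > 0)")
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name}={r} must lie strictly inside (-1, 1)")
    K = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if K <= 0:
        raise ValueError("degenerate correlation matrix (determinant <= 0)")
    rbar = (r12 + r13) / 2.0
    denom = 2 * K * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3
    t = (r12 - r13) * math.sqrt((n - 1) * (1 + r23) / denom)
    p = 2.0 * stats.t.sf(abs(t), df=n - 3)
    return WilliamsResult(t=t, p=p, df=n - 3)


def repeated_subsample_correlation(
    x,
    y,
    fraction: float = 0.25,
    replicates: int = 1000,
    seed: int | None = None,
    replace: bool = True,
) -> np.ndarray:
    """Spearman rho of repeated random subsamples of a paired sample.

    Each replicate draws ceil(fraction * n) index pairs (with replacement by
    default) and computes Spearman's rho.  Replicates whose subsample is
    degenerate (constant in either coordinate) are recorded as NaN with a
    warning rather than redrawn, so the replicate count stays transparent.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    n = len(x)
    k = math.ceil(fraction * n)
    out = np.empty(replicates)
    dropped = 0
    for i in range(replicates):
        idx = rng.integers(0, n, k) if replace else rng.permutation(n)[:k]
        xs, ys = x[idx], y[idx]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            out[i] = np.nan
            dropped += 1
        else:
            out[i] = stats.spearmanr(xs, ys).statistic
    if dropped:
        warnings.warn(
            f"{dropped}/{replicates} replicates degenerate (constant subsample)",
            RuntimeWarning,
            stacklevel=2,
        )
    return out
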