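"""Combination of dependent p-values by the weighted inverse-normal method.

Each gene's two-sided DGEA p-value ``T_i`` is mapped to its upper-tail normal
score ``t_i = Phi^{-1}(1 - T_i)``.  A common pairwise correlation ``rho``
between the scores of vicinal genes is estimated (Hartung's moment estimator,
one minus the sample variance of the scores), and the scores are pooled with
the weighted inverse-normal statistic

    t(rho) = sum(lambda_i * t_i)
             / sqrt((1 - rho) * sum(lambda_i**2) + rho * (sum(lambda_i))**2)

which is standard normal under the joint null for the true ``rho``.  The
combined p-value of a gene set is ``1 - Phi(t(rho))``: small when the set is
coherently shifted towards significance, even if no single member is
significant on its own.

A caveat that matters in practice: with equal weights the squared denominator
equals ``n * (1 + rho * (n - 1))``, which vanishes at the lower admissible
bound ``rho = -1/(n - 1)``.  Heterogeneous score sets push the moment
estimator to that bound, where the statistic is undefined (and explosive just
inside it).  ``combine_pvalues`` raises in the exactly-degenerate case; the
sub-graph search therefore scores candidates at a fixed ``rho`` (0 by
default, the Stouffer special case) — see :mod:`msfinder.search`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "CombinedScore",
    "P_EPSILON",
    "clamp_pvalue",
    "combine_pvalues",
    "combined_statistic",
    "estimate_rho",
    "normal_score",
]

#: Clamp bound for p-values before the normal-quantile transform.  Phi^{-1}
#: diverges at 0 and 1; clamping keeps scores finite while preserving order.
P_EPSILON = 1e-15


def clamp_pvalue(p: float) -> float:
    """Clamp a p-value into ``[P_EPSILON, 1 - P_EPSILON]``."""
    if not np.isfinite(p):
        raise ValueError(f"p-value must be finite, got {p!r}")
    return float(min(max(p, P_EPSILON), 1.0 - P_EPSILON))


def normal_score(p: float) -> float:
    """Upper-tail normal score ``Phi^{-1}(1 - p)`` of a p-value.

    Strictly decreasing in ``p``; 0 at ``p = 0.5``; antisymmetric about the
    median, ``normal_score(p) == -normal_score(1 - p)``.

    Parameters
    ----------
    p : float
        A p-value, already clamped to ``[P_EPSILON, 1 - P_EPSILON]``.
    """
    if not np.isfinite(p) or p <= 0.0 or p >= 1.0:
        raise ValueError(f"p-value must lie strictly inside (0, 1), got {p!r}")
    # isf(p) == Phi^{-1}(1 - p), numerically stable in the upper tail
    return float(norm.isf(p))


def estimate_rho(scores: Sequence[float]) -> float:
    """Moment estimate of the common score correlation.

    ``rho_hat = 1 - sample_variance(scores)`` (``ddof=1``), clamped to the
    admissible range ``[-1/(n-1), 1]``.  Under the equicorrelated normal
    model the scores have variance ``1 - rho``, hence the estimator.
    Identical scores (zero variance) give ``rho_hat = 1``.

    Requires ``n >= 2``; callers handle singletons separately.
    """
    t = np.asarray(scores, dtype=float)
    n = t.size
    if n < 2:
        raise ValueError("rho estimation requires at least two scores")
    raw = 1.0 - float(np.var(t, ddof=1))
    lower = -1.0 / (n - 1)
    return float(min(max(raw, lower), 1.0))


def combined_statistic(
    scores: Sequence[float],
    weights: Sequence[float],
    rho: float,
) -> float:
    """The weighted inverse-normal combined statistic ``t(rho)``.

    ``t(rho) = sum(w*t) / sqrt((1-rho)*sum(w**2) + rho*(sum(w))**2)``.

    Raises
    ------
    ValueError
        If lengths differ, a weight is non-positive, or the denominator is
        not strictly positive (only possible for ``rho`` at or outside the
        admissible range).
    """
    t = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != w.shape:
        raise ValueError("scores and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    denom_sq = (1.0 - rho) * float(np.sum(w * w)) + rho * float(np.sum(w)) ** 2
    if denom_sq <= 0.0:
        raise ValueError(
            f"combined-statistic denominator is non-positive (rho={rho!r}); "
            "rho is at or outside the admissible range"
        )
    return float(np.sum(w * t)) / float(np.sqrt(denom_sq))


@dataclass(frozen=True)
class CombinedScore:
    """Joint significance of a gene set.

    Attributes
    ----------
    statistic : float
        The combined statistic ``t(rho)``.
    rho_hat : float
        Correlation used in the denominator (0 recorded for singletons).
    combined_p : float
        ``1 - Phi(statistic)``; smaller means more coherently modulated.
    n : int
        Number of genes combined.
    weights : tuple of float
        The per-gene weights (all 1 by default).
    """

    statistic: float
    rho_hat: float
    combined_p: float
    n: int
    weights: tuple = field(default=())


def combine_pvalues(
    pvalues: Sequence[float],
    weights: Sequence[float] | None = None,
    rho: float | None = None,
) -> CombinedScore:
    """Combine dependent p-values into a single :class:`CombinedScore`.

    Parameters
    ----------
    pvalues : sequence of float
        The per-gene p-values; clamped to ``[P_EPSILON, 1 - P_EPSILON]``.
    weights : sequence of float, optional
        Positive per-gene weights; default all ones.
    rho : float, optional
        Score correlation to use.  ``None`` (default) estimates it with
        :func:`estimate_rho`; a fixed value (e.g. 0) bypasses estimation.
        Singletons always bypass estimation: the combined p-value of one
        gene is its own (clamped) p-value.
    """
    p = [clamp_pvalue(pi) for pi in pvalues]
    n = len(p)
    if n == 0:
        raise ValueError("cannot combine an empty collection of p-values")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != n:
            raise ValueError("weights must match the number of p-values")
    scores = np.array([normal_score(pi) for pi in p])
    if n == 1:
        stat = scores[0]
        rho_used = 0.0
        combined_p = p[0]
    else:
        rho_used = estimate_rho(scores) if rho is None else float(rho)
        stat = combined_statistic(scores, w, rho_used)
        combined_p = float(norm.sf(stat))
    return CombinedScore(
        statistic=float(stat),
        rho_hat=rho_used,
        combined_p=combined_p,
        n=n,
        weights=tuple(float(x) for x in w),
    )
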