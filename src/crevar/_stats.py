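"""Shared statistical primitives.

Small, well-specified building blocks used across the linking, STARR and
prioritization modules: Benjamini-Hochberg adjustment, Fisher's combined
probability, two-sided Wilcoxon rank-sum (exact enumeration for small
groups, midrank normal approximation with continuity correction
otherwise), one-sided Poisson tail probabilities with a continuous
extension for non-integer counts, and the linear-interpolation sample
quantile.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

#: smallest reported p value; avoids log(0) in downstream combination
P_FLOOR = float(np.finfo(np.float64).tiny)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (FDR), preserving input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(pvals, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Fisher's method: statistic -2*sum(ln p) and chi-square p (2k df).

    Returns ``(statistic, combined_p)``; reduces over ``axis``.
    """
    p = np.clip(np.asarray(pvals, dtype=float), P_FLOOR, 1.0)
    k = p.shape[axis] if p.ndim else 1
    stat = -2.0 * np.sum(np.log(p), axis=axis)
    return stat, stats.chi2.sf(stat, df=2 * k)


def poisson_tail(k, rate, side: str) -> np.ndarray:
    """One-sided Poisson tail probability, continuous in ``k``.

    ``side='lower'`` gives P(X <= k) = Q(k+1, rate) and ``side='upper'``
    gives P(X >= k) = P(k, rate), via regularized incomplete gamma
    functions; for integer ``k`` these coincide with the discrete tails,
    and for fractional ``k`` (fold-averaged counts) they interpolate
    smoothly.
    """
    k = np.asarray(k, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("Poisson rate must be nonnegative")
    if side == "lower":
        return special.gammaincc(k + 1.0, rate)
    if side == "upper":
        # P(X >= 0) == 1 by convention; gammainc(0, .) is undefined
        return np.where(k <= 0, 1.0, special.gammainc(np.maximum(k, P_FLOOR), rate))
    raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")


def signed_poisson_pvalue(alt, ref) -> np.ndarray:
    """One-sided Poisson p of ``alt`` under rate ``ref``, tail by sign.

    Upper tail when alt > ref, lower tail when alt < ref, 1.0 when equal.
    """
    alt = np.asarray(alt, dtype=float)
    ref = np.asarray(ref, dtype=float)
    out = np.ones(np.broadcast(alt, ref).shape, dtype=float)
    up = alt > ref
    lo = alt < ref
    if np.any(up):
        out[up] = poisson_tail(alt[up], np.broadcast_to(ref, out.shape)[up], "upper")
    if np.any(lo):
        out[lo] = poisson_tail(alt[lo], np.broadcast_to(ref, out.shape)[lo], "lower")
    return out


def _rank_sum_statistic(pooled_ranks: np.ndarray, idx) -> float:
    return float(pooled_ranks[list(idx)].sum())


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all label assignments.

    Uses midranks, so ties are handled exactly. The two-sided p is the
    null fraction of assignments whose rank-sum deviates from its mean at
    least as much as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n = len(x), len(x) + len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-9
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(_rank_sum_statistic(ranks, idx) - mu) >= dev:
            count += 1
    return count / total


def rank_sum_p(x, y, exact_max: int = 5) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact enumeration when both groups have at most ``exact_max``
    observations; otherwise the midrank normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return 1.0
    if len(x) <= exact_max and len(y) <= exact_max:
        return exact_rank_sum_p(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def rank_sum_p_batch(x: np.ndarray, y: np.ndarray, exact_max: int = 5) -> np.ndarray:
    """Column-wise two-sided rank-sum p for matrices ``x`` (n1 x F), ``y`` (n2 x F)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] <= exact_max and y.shape[0] <= exact_max:
        return np.array([exact_rank_sum_p(x[:, j], y[:, j]) for j in range(x.shape[1])])
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=0)
    return np.asarray(res.pvalue, dtype=float)


def sample_quantile(values, q: float) -> float:
    """Linear-interpolation sample quantile (the common 'type 7' default)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    if not 0.0 <= q <= 1.0:
        raise ValueError("quantile level must lie in [0, 1]")
    return float(np.quantile(values, q))


def log2_fold_change(mean_a, mean_b, eps: float = 1.0) -> np.ndarray:
    """log2((mean_a + eps) / (mean_b + eps)); eps guards empty groups."""
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    return np.log2(mean_a + eps) - np.log2(mean_b + eps)


def round_half_even(value: float, ndigits: int = 1) -> float:
    """Round half to even, matching the reporting convention for percentages."""
    return float(np.format_float_positional(value, precision=ndigits,
                                            unique=False, fractional=True))


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-even to one decimal place."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_even(100.0 * numerator / denominator, 1)
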