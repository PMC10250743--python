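"""Paired Wilcoxon signed-rank test with exact tie-aware p-values.

Every between-device comparison in the pipeline — band powers, per-action
power, time-frequency bins, Likert comfort scores — is a paired Wilcoxon
signed-rank test across subjects. Cohorts here are small (6-10 subjects),
where the exact null distribution matters: the test statistic W (sum of
positive signed ranks) is discrete and normal approximations are poor.

The exact distribution is computed by dynamic programming over the rank
multiset (equivalent to full enumeration of the 2^m sign assignments but
polynomial time), which remains correct under midranks for tied |d|.
Zero differences are discarded (classic Wilcoxon convention); if all
differences are zero the test is degenerate and p = 1 by convention.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata

#: Above this many non-zero differences, switch to the normal
#: approximation with tie correction and continuity correction.
EXACT_CUTOFF = 25

_ALTERNATIVES = ("two-sided", "greater", "less")


class InsufficientDataError(ValueError):
    """Too few (effective) pairs for the requested statistic."""


def _exact_sf_cdf(scaled_ranks: np.ndarray, w2: int):
    """Return (P(W2 <= w2), P(W2 >= w2)) for W2 = sum of a random subset of
    ``scaled_ranks`` (each included with prob 1/2), all integers."""
    total = int(scaled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in scaled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    cdf = float(counts[: w2 + 1].sum())
    sf = float(counts[w2:].sum())
    return cdf, sf


def wilcoxon_signed_rank(x, y, alternative: str = "two-sided",
                         exact_cutoff: int = EXACT_CUTOFF):
    """Paired Wilcoxon signed-rank test of ``x`` vs ``y``.

    Parameters
    ----------
    x, y : array-like, same length
        One paired observation per subject.
    alternative : {"two-sided", "greater", "less"}
        "greater" tests for x tending to exceed y.

    Returns
    -------
    W : float
        Sum of the ranks of positive differences (midranks for ties).
    p : float
        Exact p-value (rank-distribution enumeration) for up to
        ``exact_cutoff`` non-zero differences, else a normal approximation
        with tie and continuity corrections.

    Notes
    -----
    Zero differences are discarded before ranking. ``x == y`` everywhere
    returns (0.0, 1.0) by documented convention. At least 2 pairs must be
    supplied.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 pairs")
    d = x - y
    d = d[d != 0]
    m = len(d)
    if m == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())

    if m <= exact_cutoff:
        # Midranks are multiples of 1/2: scale by 2 onto an integer grid.
        scaled = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * w))
        cdf, sf = _exact_sf_cdf(scaled, w2)
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(cdf, sf))
        return w, p

    # Normal approximation with tie correction and continuity correction.
    mu = m * (m + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / 48.0
    sigma = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0 - tie_term)
    if alternative == "greater":
        p = norm.sf((w - mu - 0.5) / sigma)
    elif alternative == "less":
        p = norm.cdf((w - mu + 0.5) / sigma)
    else:
        z = (w - mu - np.sign(w - mu) * 0.5) / sigma
        p = 2 * norm.sf(abs(z))
    return w, float(min(1.0, p))


def exact_null_pvalues(n: int) -> np.ndarray:
    """Two-sided exact p-value for each achievable W = 0..n(n+1)/2 with
    ``n`` untied non-zero differences.

    Used to vectorize bin-wise map comparisons: with continuous data the
    ranks are 1..n, so p depends only on (n, W).
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    cdf = np.cumsum(counts)
    sf = np.cumsum(counts[::-1])[::-1]
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def sem(values) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise InsufficientDataError("sem needs at least 2 values")
    return float(np.std(v, ddof=1) / np.sqrt(len(v)))


def median_direction(x, y) -> int:
    """Sign of the median paired difference (+1, 0, -1)."""
    return int(np.sign(np.median(np.asarray(x, float) - np.asarray(y, float))))
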