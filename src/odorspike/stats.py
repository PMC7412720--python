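"""Nonparametric tests with exact small-sample behavior.

Thin, policy-carrying wrappers around :mod:`scipy.stats`: two-sided
throughout; zero differences discarded before ranking (signed-rank); ties
receive average ranks; p-values are exact by enumeration whenever the
sample is small (n <= 25) and tie-free, otherwise a tie-corrected normal
approximation is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n: int
    method: str  # "exact", "normal-approx", or "degenerate"
    n2: Optional[int] = None  # second sample size for two-sample tests


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ by enumeration of all sign assignments.

    Conditional on the observed (average, possibly tied) ranks: the null
    distribution of W+ is the convolution of independent two-point
    distributions {0, r_i}.  Average ranks are half-integers, so doubling
    makes every support point an integer and the distribution is computed
    by polynomial products.  Two-sided p = 2 * min(lower, upper tail),
    capped at 1; the distribution is symmetric under the null.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(round(2 * w_plus))
    lower = pmf[: w2 + 1].sum()
    upper = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(differences: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are discarded before ranking; ties receive average ranks.  For
    n <= 25 the p-value is exact by enumeration of the 2**n sign
    assignments conditional on the observed ranks (ties do not block the
    exact path); larger samples use the tie-corrected normal
    approximation.  Returns the W+ rank sum as the statistic.  With no
    nonzero differences the result is degenerate: p = 1.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("wilcoxon_signed_rank requires at least one difference")
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        return TestResult(statistic=0.0, p=1.0, n=0, method="degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        res = sps.wilcoxon(d, alternative="two-sided", method="approx", correction=False)
        p, method = float(res.pvalue), "normal-approx"
    return TestResult(statistic=w_plus, p=float(min(p, 1.0)), n=n, method=method)


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    The statistic is U for ``sample_a``; U + U' = n1 * n2.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u requires two nonempty samples")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        # every observation tied: U sits exactly at its null mean
        return TestResult(
            statistic=float(a.size * b.size / 2),
            p=1.0,
            n=int(a.size),
            n2=int(b.size),
            method="degenerate",
        )
    exact = (
        a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and not _has_ties(combined)
    )
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return TestResult(
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        n=int(a.size),
        n2=int(b.size),
        method="exact" if exact else "normal-approx",
    )
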