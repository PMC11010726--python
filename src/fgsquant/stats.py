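"""Two-sample and paired location tests with exact small-sample p-values.

Small cohorts (a handful of animals per model) dominate this kind of
study, so the Mann-Whitney U and Wilcoxon signed-rank tests are computed
from their exact permutation distributions whenever feasible:

* Mann-Whitney — the full distribution of the rank sum over all C(n+m, n)
  assignments of ranks to the first sample, used when n + m <= 12 and the
  pooled data contain no ties;
* Wilcoxon signed-rank — the distribution of the positive-rank sum over
  all 2^n sign patterns of the observed ranks (valid with midranks), used
  when the number of non-zero differences is <= 20.

Outside the exact regime a normal approximation with tie and continuity
corrections is used, and the choice is recorded in ``TestResult.method``.
All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

from .errors import DegenerateDataError, InputError

__all__ = [
    "TestResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "paired_t",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float  # two-sided, in (0, 1]
    n: int
    m: Optional[int] = None
    method: str = "exact"  # "exact" | "approximate"


# ---------------------------------------------------------------- Mann-Whitney

def _rank_sum_counts(n: int, N: int) -> np.ndarray:
    """counts[s] = number of n-subsets of {1..N} with rank sum s."""
    max_sum = n * N
    # dp[k, s]: number of k-subsets with sum s; roll over ranks 1..N
    dp = np.zeros((n + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, N + 1):
        dp[1:, r:] += dp[:-1, :-r or None].copy()
    return dp[n]


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U test (U statistic of the first sample).

    Exact two-sided p by enumeration of rank arrangements when
    n + m <= 12 and there are no ties; otherwise normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise InputError("both samples must contain at least one value")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n].sum()
    u1 = r1 - n * (n + 1) / 2.0
    N = n + m
    has_ties = np.unique(pooled).size < N

    if N <= 12 and not has_ties:
        counts = _rank_sum_counts(n, N)
        total = counts.sum()
        offset = n * (n + 1) // 2  # rank sum s corresponds to U = s - offset
        u_int = int(round(u1))
        le = counts[: offset + u_int + 1].sum()
        ge = counts[offset + u_int:].sum()
        p = min(1.0, 2.0 * min(le, ge) / total)
        return TestResult(float(u1), float(p), n, m, "exact")

    mu = n * m / 2.0
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = (t_counts**3 - t_counts).sum()
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # all observations identical
        return TestResult(float(u1), 1.0, n, m, "approximate")
    diff = u1 - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return TestResult(float(u1), float(p), n, m, "approximate")


# ---------------------------------------------------- Wilcoxon signed-rank

def _signed_rank_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """counts[s] = number of sign patterns with doubled positive-rank sum s."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in doubled_ranks:
        r = int(r)
        counts[r:] += counts[:-r or None].copy()
    return counts


def wilcoxon_signed_rank(paired_a: Sequence[float],
                         paired_b: Sequence[float]) -> TestResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded (classic convention); W is the sum of
    the ranks of positive differences among |differences| (midranks for
    ties).  Exact two-sided p by enumeration of the 2^n sign patterns when
    the number of non-zero differences is <= 20, otherwise normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size:
        raise InputError("paired samples must have equal length")
    if a.size < 2:
        raise InputError("need at least two pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())

    if n <= 20:
        doubled = np.round(2 * ranks).astype(np.int64)
        counts = _signed_rank_counts(doubled)
        total = counts.sum()  # 2**n
        w2 = int(round(2 * w))
        le = counts[: w2 + 1].sum()
        ge = counts[w2:].sum()
        p = min(1.0, 2.0 * min(le, ge) / total)
        return TestResult(w, float(p), n, method="exact")

    mu = n * (n + 1) / 4.0
    _, t_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - \
        (t_counts**3 - t_counts).sum() / 48.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return TestResult(w, float(p), n, method="approximate")


# ------------------------------------------------------------------ paired t

def paired_t(paired_a: Sequence[float],
             paired_b: Sequence[float]) -> TestResult:
    """Paired t test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size:
        raise InputError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise InputError("need at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("paired differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = min(1.0, float(2.0 * t_dist.sf(abs(t), n - 1)))
    return TestResult(float(t), p, n, method="exact")
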