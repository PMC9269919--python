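"""Exact small-sample nonparametric tests.

Both tests compute exact two-sided p-values on the full discrete null
distribution — every sign assignment for the Wilcoxon signed-rank test,
every group assignment for the Mann-Whitney U test — via subset-sum dynamic
programming in integer arithmetic (equivalent to full enumeration at any
sample size).  The two-sided p-value convention is

    p = min(1, 2 * min(lower tail, upper tail)),

with tails inclusive of the observed statistic.  Ties receive midranks
(flagged in the result); zero differences are dropped before ranking, per
Wilcoxon's original prescription, and their count is reported.

A normal-approximation p-value is available behind ``method="normal"`` as a
cross-check only; it is never the default at the sample sizes this package
targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
from scipy import stats

from .core import ValidationError


@dataclass
class ExactTestResult:
    statistic: float
    p_two_sided: float
    method: str
    n: int | None = None
    n1: int | None = None
    n2: int | None = None
    tie_note: bool = False
    n_zeros_dropped: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _doubled_ranks(ranks: np.ndarray) -> list[int]:
    """Midranks doubled to integers (midranks are multiples of 1/2)."""
    r2 = np.rint(2.0 * ranks).astype(int)
    assert np.allclose(r2 / 2.0, ranks)
    return r2.tolist()


def _signed_rank_counts(r2: list[int]) -> list[int]:
    """counts[s] = number of sign assignments whose positive-rank sum
    (doubled) equals s; integer arithmetic, total = 2**n."""
    total = sum(r2)
    counts = [0] * (total + 1)
    counts[0] = 1
    for r in r2:
        for s in range(total, r - 1, -1):
            counts[s] += counts[s - r]
    return counts


def _two_sided_p(counts: list[int], observed: int, total: int) -> float:
    lower = sum(counts[: observed + 1])
    upper = sum(counts[observed:])
    return min(1.0, 2.0 * min(lower, upper) / total)


def wilcoxon_signed_rank_exact(differences, method: str = "exact") -> ExactTestResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    The statistic is W+, the sum of ranks of the positive differences among
    the ranked absolute differences.  The exact null enumerates all 2**n
    equally likely sign assignments.
    """
    d = np.asarray(list(differences), dtype=float)
    if d.size == 0 or not np.all(np.isfinite(d)):
        raise ValidationError("differences must be a non-empty finite sequence")
    nz = d[d != 0]
    n_zeros = int(d.size - nz.size)
    if nz.size == 0:
        raise ValidationError("all differences are zero: test undefined")
    n = int(nz.size)
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    ties = len(np.unique(np.abs(nz))) < n
    if method == "normal":
        # large-sample cross-check only
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        z = (w_plus - mean) / sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    elif method == "exact":
        r2 = _doubled_ranks(ranks)
        counts = _signed_rank_counts(r2)
        p = _two_sided_p(counts, int(round(2 * w_plus)), 2**n)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return ExactTestResult(
        statistic=w_plus,
        p_two_sided=p,
        method=f"signed_rank_{method}",
        n=n,
        tie_note=ties,
        n_zeros_dropped=n_zeros,
    )


def _rank_sum_counts(r2: list[int], n1: int) -> list[int]:
    """counts[s] = number of size-n1 subsets of the doubled ranks with sum s;
    total = C(n, n1)."""
    total = sum(r2)
    dp = [[0] * (total + 1) for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in r2:
        for c in range(min(n1, len(r2)), 0, -1):
            row, prev = dp[c], dp[c - 1]
            for s in range(total, r - 1, -1):
                if prev[s - r]:
                    row[s] += prev[s - r]
    return dp[n1]


def mann_whitney_u_exact(sample_a, sample_b, method: str = "exact") -> ExactTestResult:
    """Exact two-sided Mann-Whitney U test between two independent samples.

    The statistic is U1, the number of (a, b) pairs with a > b (ties count
    half).  The exact null enumerates all C(n1+n2, n1) assignments of the
    pooled ranks to group a.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("sample values must be finite")
    n1, n2 = int(a.size), int(b.size)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w1 = float(ranks[:n1].sum())
    u1 = w1 - n1 * (n1 + 1) / 2.0
    ties = len(np.unique(pooled)) < n1 + n2
    if method == "normal":
        mean = n1 * n2 / 2.0
        var = n1 * n2 * (n1 + n2 + 1) / 12.0
        z = (u1 - mean) / sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    elif method == "exact":
        r2 = _doubled_ranks(ranks)
        counts = _rank_sum_counts(r2, n1)
        p = _two_sided_p(counts, int(round(2 * w1)), comb(n1 + n2, n1))
    else:
        raise ValidationError(f"unknown method {method!r}")
    return ExactTestResult(
        statistic=u1,
        p_two_sided=p,
        method=f"mann_whitney_{method}",
        n1=n1,
        n2=n2,
        tie_note=ties,
    )
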