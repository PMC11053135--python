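"""Exact small-sample nonparametric tests and summary statistics.

The mapping experiments rest on three rank tests applied to tiny samples
(five animals, three-to-five sites per group): the paired Wilcoxon
signed-rank test, the unpaired Mann-Whitney U test, and the Kruskal-Wallis
test followed by Dunn's pairwise post-hoc comparisons.  At these sample
sizes asymptotic p-values are unreliable, so the signed-rank and U tests
are computed *exactly* by enumerating the full null distribution of the
rank statistic (all ``2^m`` sign assignments, respectively all
``C(n1+n2, n1)`` labelings of the pooled midranks).  Enumeration is done
with an integer dynamic program over doubled midranks, so ties are handled
exactly and the cost is polynomial rather than exponential.

Conventions
-----------
* Midranks are used for ties throughout.
* Zero differences are dropped before the signed-rank test (Wilcoxon's
  original convention).
* The exact two-sided p-value is ``min(1, 2 * min(lower tail, upper tail))``
  (the "doubling" convention).  Under complete separation this yields
  2/C(n1+n2, n1), e.g. 0.0159 for group sizes (4, 5) and 0.0357 for (3, 5).
* Sidedness is never inferred from the data; callers must state it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm, rankdata

from .errors import DegenerateTestError, ParameterError

__all__ = [
    "StatResult",
    "SummaryStat",
    "wilcoxon_exact",
    "mannwhitney_exact",
    "kruskal_wallis",
    "dunn_posthoc",
    "mean_se",
    "round_half_up",
]

_ALTERNATIVES = ("two-sided", "greater", "less")

#: largest single-group size for which enumeration is attempted under
#: ``method="auto"``; beyond this the normal approximation is used.
EXACT_LIMIT = 25


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test.

    ``statistic_name`` identifies the convention of ``statistic``
    (W = positive-rank sum, U = Mann-Whitney U of the first sample,
    H = Kruskal-Wallis statistic, z = standard-normal score).
    """

    test: str
    statistic: float
    p_value: float
    alternative: str
    n: tuple[int, ...]
    exact: bool
    tie_corrected: bool = False
    statistic_name: str = ""
    pair: tuple[int, int] | None = None
    adjustment: str | None = None


@dataclass(frozen=True)
class SummaryStat:
    """Mean +/- standard error of the mean."""

    mean: float
    se: float
    n: int
    degenerate: bool = False  # n == 1: SE set to 0 by convention


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ParameterError(
            f"alternative must be one of {_ALTERNATIVES}, got {alternative!r}"
        )


def _doubled_ranks(values: np.ndarray) -> np.ndarray:
    """Midranks scaled by 2 so that tied midranks become exact integers."""
    r2 = np.rint(2.0 * rankdata(values)).astype(np.int64)
    return r2


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as p-values are printed in reports.

    Python's builtin ``round`` is banker's rounding: ``round(0.03125, 4)``
    gives 0.0312, whereas the conventional printed value is 0.0313.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_counts(r2: np.ndarray) -> np.ndarray:
    """Null counts of the doubled positive-rank sum over all 2^m sign vectors.

    ``counts[s]`` = number of sign assignments with doubled rank sum s.
    Total mass is 2^m, which stays exactly representable in int64 for the
    sample sizes where enumeration is used (m <= 25 by default, and int64
    is exact up to m = 62).
    """
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in r2:
        r = int(r)
        counts[r:] = counts[r:] + counts[: counts.size - r]
    return counts


def wilcoxon_exact(
    a,
    b=None,
    alternative: str = "two-sided",
    method: str = "auto",
) -> StatResult:
    """Paired Wilcoxon signed-rank test with an exact enumerated p-value.

    Parameters
    ----------
    a, b
        Paired samples.  If ``b`` is omitted, ``a`` is taken to be the
        vector of paired differences directly.
    alternative
        "greater" tests whether ``a`` tends to exceed ``b``.
    method
        "exact" forces enumeration, "approx" forces the tie-corrected
        normal approximation, "auto" enumerates for m <= EXACT_LIMIT
        nonzero differences.

    Raises
    ------
    DegenerateTestError
        If every paired difference is zero.
    """
    _check_alternative(alternative)
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ParameterError("need at least one pair")
    n_pairs = d.size
    d = d[d != 0]  # drop zero differences (Wilcoxon convention)
    m = d.size
    if m == 0:
        raise DegenerateTestError("all paired differences are zero")

    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    r2 = _doubled_ranks(np.abs(d))
    w2 = int(round(2.0 * w))

    exact = method == "exact" or (method == "auto" and m <= EXACT_LIMIT)
    if exact:
        counts = _signed_rank_counts(r2)
        total = float(2**m)
        p_ge = float(counts[w2:].sum()) / total
        p_le = float(counts[: w2 + 1].sum()) / total
    else:
        # normal approximation with tie correction
        mu = m * (m + 1) / 4.0
        _, t = np.unique(ranks, return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(t**3 - t) / 48.0
        sd = math.sqrt(var)
        p_ge = float(norm.sf((w - 0.5 - mu) / sd))
        p_le = float(norm.cdf((w + 0.5 - mu) / sd))

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return StatResult(
        test="wilcoxon",
        statistic=w,
        p_value=p,
        alternative=alternative,
        n=(n_pairs,),
        exact=exact,
        tie_corrected=bool(np.unique(np.abs(d)).size < m),
        statistic_name="W",
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _rank_sum_counts(r2: np.ndarray, n1: int) -> np.ndarray:
    """Null counts of the doubled first-sample rank sum over all labelings.

    ``counts[s]`` = number of size-``n1`` subsets of the pooled doubled
    midranks with sum s.  Total mass C(n, n1).
    """
    total = int(r2.sum())
    # dp[k, s]: subsets of size k summing to s
    dp = np.zeros((n1 + 1, total + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in r2:
        r = int(r)
        for k in range(n1, 0, -1):
            dp[k, r:] = dp[k, r:] + dp[k - 1, : total + 1 - r]
    return dp[n1]


def mannwhitney_exact(
    x,
    y,
    alternative: str = "two-sided",
    method: str = "auto",
) -> StatResult:
    """Unpaired Mann-Whitney (Wilcoxon rank-sum) test, exact by enumeration.

    "greater" tests whether ``x`` tends to exceed ``y``.  The reported
    statistic is U for the first sample.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    exact = method == "exact" or (method == "auto" and min(n1, n2) <= EXACT_LIMIT)
    if exact and math.comb(n1 + n2, n1) > 2**62:
        exact = False  # counts would overflow int64
    if exact:
        r2 = _doubled_ranks(pooled)
        counts = _rank_sum_counts(r2, n1)
        total = float(math.comb(n1 + n2, n1))
        s_obs = int(round(2.0 * r1))
        p_ge = float(counts[s_obs:].sum()) / total
        p_le = float(counts[: s_obs + 1].sum()) / total
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        _, t = np.unique(ranks, return_counts=True)
        tie = np.sum(t**3 - t) / ((n * (n - 1)) if n > 1 else 1.0)
        var = n1 * n2 / 12.0 * ((n + 1) - tie)
        sd = math.sqrt(var)
        p_ge = float(norm.sf((u1 - 0.5 - mu) / sd))
        p_le = float(norm.cdf((u1 + 0.5 - mu) / sd))

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return StatResult(
        test="mannwhitney",
        statistic=u1,
        p_value=p,
        alternative=alternative,
        n=(n1, n2),
        exact=exact,
        tie_corrected=bool(np.unique(pooled).size < n1 + n2),
        statistic_name="U",
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn's post hoc
# ---------------------------------------------------------------------------

def _kw_h(groups: list[np.ndarray]) -> tuple[float, bool]:
    """Tie-corrected Kruskal-Wallis H for a list of samples."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled)
    if np.unique(pooled).size == 1:
        return 0.0, False
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t**3 - t))
    corrected = tie_term > 0
    if corrected:
        h /= 1.0 - tie_term / (n**3 - n)
    return float(h), corrected


def _label_assignments(n: int, sizes: tuple[int, ...]):
    """Yield index tuples partitioning range(n) into groups of the given sizes."""

    def rec(remaining: frozenset, sizes):
        if not sizes:
            yield ()
            return
        k = sizes[0]
        for combo in itertools.combinations(sorted(remaining), k):
            for rest in rec(remaining - set(combo), sizes[1:]):
                yield (combo,) + rest

    yield from rec(frozenset(range(n)), sizes)


def kruskal_wallis(groups, method: str = "chi2") -> StatResult:
    """Kruskal-Wallis rank test across >= 2 independent groups.

    ``method="chi2"`` (default) uses the chi-square approximation with
    k - 1 degrees of freedom; ``method="permutation"`` enumerates every
    assignment of the pooled values to the group sizes (only feasible for
    pooled n <= ~12) and is provided for tiny-sample checks.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ParameterError("need >= 2 non-empty groups")
    sizes = tuple(g.size for g in groups)
    pooled = np.concatenate(groups)
    h, corrected = _kw_h(groups)
    df = len(groups) - 1

    if np.unique(pooled).size == 1:
        return StatResult("kruskal", 0.0, 1.0, "two-sided", sizes, True,
                          tie_corrected=False, statistic_name="H")

    if method == "chi2":
        p = float(chi2.sf(h, df))
        exact = False
    elif method == "permutation":
        if pooled.size > 12:
            raise ParameterError("permutation enumeration limited to pooled n <= 12")
        count = 0
        total = 0
        for assignment in _label_assignments(pooled.size, sizes):
            perm = [pooled[list(idx)] for idx in assignment]
            h_perm, _ = _kw_h(perm)
            count += h_perm >= h - 1e-12
            total += 1
        p = count / total
        exact = True
    else:
        raise ParameterError(f"unknown method {method!r}")
    return StatResult(
        test="kruskal",
        statistic=h,
        p_value=p,
        alternative="two-sided",
        n=sizes,
        exact=exact,
        tie_corrected=corrected,
        statistic_name="H",
    )


def dunn_posthoc(groups, adjustment: str = "none") -> list[StatResult]:
    """Dunn's pairwise z comparisons on the pooled midranks.

    For groups i, j the statistic is
    ``z = (rbar_i - rbar_j) / sqrt(A * (1/n_i + 1/n_j))`` with the
    tie-corrected pooled variance term
    ``A = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1))``.
    Two-sided normal p-values; optional Bonferroni or Holm adjustment over
    the ``k(k-1)/2`` pairs.
    """
    if adjustment not in ("none", "bonferroni", "holm"):
        raise ParameterError(f"unknown adjustment {adjustment!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ParameterError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled)
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t**3 - t))
    a = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start : start + g.size].mean()))
        start += g.size

    raw: list[StatResult] = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        ni, nj = groups[i].size, groups[j].size
        denom = math.sqrt(a * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        p = float(2.0 * norm.sf(abs(z)))
        raw.append(StatResult(
            test="dunn",
            statistic=z,
            p_value=p,
            alternative="two-sided",
            n=(ni, nj),
            exact=False,
            tie_corrected=tie_term > 0,
            statistic_name="z",
            pair=(i, j),
            adjustment=adjustment,
        ))

    if adjustment == "none":
        return raw
    k = len(raw)
    if adjustment == "bonferroni":
        adj = [min(1.0, r.p_value * k) for r in raw]
    else:  # holm step-down
        order = sorted(range(k), key=lambda i: raw[i].p_value)
        adj = [0.0] * k
        running = 0.0
        for rank_i, idx in enumerate(order):
            val = min(1.0, (k - rank_i) * raw[idx].p_value)
            running = max(running, val)
            adj[idx] = running
    return [
        StatResult(r.test, r.statistic, p, r.alternative, r.n, r.exact,
                   r.tie_corrected, r.statistic_name, r.pair, adjustment)
        for r, p in zip(raw, adj)
    ]


def mean_se(values) -> SummaryStat:
    """Mean and standard error (sample SD / sqrt(n)); SE = 0 for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("need at least one value")
    if v.size == 1:
        return SummaryStat(float(v[0]), 0.0, 1, degenerate=True)
    return SummaryStat(float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size)),
                       int(v.size))
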