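"""Independent brute-force oracles for the exact rank tests.

These enumerate the null distributions literally (all sign vectors, all
group labelings) with no shared code with the package implementation.
"""

import itertools

import numpy as np
from scipy.stats import rankdata


def wilcoxon_brute(a, b, alternative="two-sided"):
    """Exact signed-rank p by explicit enumeration of all 2^m sign vectors."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    m = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = 0
    total = 0
    for signs in itertools.product((1, -1), repeat=m):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        ge += w >= w_obs - 1e-12
        le += w <= w_obs + 1e-12
        total += 1
    p_ge, p_le = ge / total, le / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def mannwhitney_brute(x, y, alternative="two-sided"):
    """Exact rank-sum p by explicit enumeration of all C(n1+n2, n1) labelings."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_obs = ranks[:n1].sum()
    ge = le = total = 0
    for combo in itertools.combinations(range(pooled.size), n1):
        r = ranks[list(combo)].sum()
        ge += r >= r_obs - 1e-12
        le += r <= r_obs + 1e-12
        total += 1
    p_ge, p_le = ge / total, le / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def kruskal_h_formula(groups):
    """H from the rank-sum formula with explicit tie correction."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    tie = np.sum(t.astype(float) ** 3 - t)
    if tie > 0:
        h /= 1.0 - tie / (n**3 - n)
    return h
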