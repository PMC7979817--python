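"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops, closed forms, or exhaustive
enumeration — deliberately independent of the package's vectorized paths
(and of the scipy calls the package makes for combinatorial tails).
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np


def pearson_loop(x, y) -> float:
    """Textbook Pearson correlation, scalar arithmetic only."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def fisher_z_loop(block, clip=1e-7) -> list[float]:
    """Per-pair Pearson then atanh, looping over the upper triangle."""
    nn = len(block)
    out = []
    for i in range(nn):
        for j in range(i + 1, nn):
            r = pearson_loop(block[i], block[j])
            r = max(-1 + clip, min(1 - clip, r))
            out.append(math.atanh(r))
    return out


def t_pvalue_loop(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r via the t-transform; the tail integral
    uses the regularized incomplete beta through mpmath-free math.betainc
    (Python 3.11+)."""
    df = n - 2
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * math.sqrt(df / (1 - r * r))
    # survival of |T| ~ t_df: P(|T| > t) = betainc(df/2, 1/2, df/(df+t^2))
    xx = df / (df + t * t)
    from scipy.special import betainc  # independent of stats.t machinery

    return float(betainc(df / 2.0, 0.5, xx))


def select_edges_loop(E, y, alpha):
    """Per-edge loop: Pearson, t-transform p, strict threshold, sign split."""
    n, m = E.shape
    pos, neg = [], []
    for e in range(m):
        col = E[:, e]
        if np.std(col, ddof=1) == 0 or np.isnan(col).any():
            continue
        r = pearson_loop(col, y)
        if t_pvalue_loop(r, n) < alpha:
            (pos if r > 0 else neg).append(e)
    return sorted(pos), sorted(neg)


def strength_loop(values, pos, neg) -> float:
    s = 0.0
    for e in pos:
        s += values[e]
    for e in neg:
        s -= values[e]
    return s


def ols_loop(s, y):
    """Closed-form normal equations for y = beta*s + c."""
    n = len(s)
    sm = sum(s) / n
    ym = sum(y) / n
    beta = sum((a - sm) * (b - ym) for a, b in zip(s, y)) / sum((a - sm) ** 2 for a in s)
    return beta, ym - beta * sm


def partial_corr_formula(x, y, z) -> float:
    """Recursive 3-variable partial correlation r_xy.z."""
    rxy = pearson_loop(x, y)
    rxz = pearson_loop(x, z)
    ryz = pearson_loop(y, z)
    return (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))


def signed_rank_exact(diffs) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n sign
    assignments. Requires no zeros and no tied absolute values."""
    d = [x for x in diffs]
    assert all(x != 0 for x in d)
    absd = sorted(abs(x) for x in d)
    assert len(set(absd)) == len(absd), "oracle requires untied |d|"
    ranks = {v: i + 1 for i, v in enumerate(absd)}
    w_plus = sum(ranks[abs(x)] for x in d if x > 0)
    n = len(d)
    total = sum(r for r in range(1, n + 1))
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(range(1, n + 1), signs) if s)
        if min(w, total - w) <= w_obs:
            count += 1
    return min(1.0, count / 2**n)


def ranksum_exact(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all group-A rank sets.
    Requires no ties across the pooled sample."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    ra = sum(ranks[v] for v in a)
    na, nb = len(a), len(b)
    mean_ra = na * (na + nb + 1) / 2
    dev_obs = abs(ra - mean_ra)
    count = 0
    total = 0
    for combo in combinations(range(1, na + nb + 1), na):
        total += 1
        if abs(sum(combo) - mean_ra) >= dev_obs - 1e-12:
            count += 1
    return count / total


def bh_adjust_loop(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, plain loops."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj


def hypergeom_strict_tail(x, M, K, n) -> float:
    """P(X > x) for X ~ Hypergeometric(M, K, n), by direct summation of
    binomial-coefficient ratios."""
    denom = math.comb(M, n)
    total = 0
    for k in range(x + 1, min(K, n) + 1):
        total += math.comb(K, k) * math.comb(M - K, n - k)
    return total / denom


def spearman_loop(x, y) -> float:
    """Rank (average ties) then Pearson."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    return pearson_loop(avg_ranks(list(x)), avg_ranks(list(y)))
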