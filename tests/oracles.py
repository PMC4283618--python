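"""Brute-force oracles, kept independent of the implementation paths.

Fisher's exact test is enumerated over all tables with the observed margins
using exact rational arithmetic; the rank tests are re-derived by label
permutation; the two-way variance components are recomputed from explicit
loop-based sums of squares.
"""

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats


def fisher_two_sided_enumeration(table) -> float:
    """Point-probability two-sided Fisher p by full hypergeometric
    enumeration with Fraction arithmetic."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p_x <= p_obs:
            total += p_x
    return float(total)


def chi2_by_hand(table) -> tuple[float, int]:
    """Pearson chi-square statistic and df from first principles."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - e) ** 2 / e
    return stat, (t.shape[0] - 1) * (t.shape[1] - 1)


def _midrank_u(x, y) -> float:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def permutation_mw_p(x, y, n_perm=20000, seed=0) -> float:
    """Two-sided Mann-Whitney p by permuting group labels."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    centre = n1 * len(y) / 2.0
    obs = abs(_midrank_u(x, y) - centre)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        hits += abs(_midrank_u(pooled[:n1], pooled[n1:]) - centre) >= obs - 1e-9
    return (hits + 1) / (n_perm + 1)


def permutation_kw_p(groups, n_perm=20000, seed=0) -> float:
    """Kruskal-Wallis p by permuting group labels (H recomputed per draw)."""
    arrays = [np.asarray(g, float) for g in groups]
    sizes = [len(g) for g in arrays]
    pooled = np.concatenate(arrays)

    def h_stat(values):
        ranks = stats.rankdata(values)
        n = len(values)
        start = 0
        h = 0.0
        for s in sizes:
            rg = ranks[start : start + s]
            h += rg.sum() ** 2 / s
            start += s
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        # tie correction
        _, counts = np.unique(values, return_counts=True)
        correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
        return h / correction if correction > 0 else 0.0

    obs = h_stat(pooled)
    rng = np.random.default_rng(seed)
    hits = 0
    work = pooled.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        hits += h_stat(work) >= obs - 1e-9
    return (hits + 1) / (n_perm + 1)


def anova_components_by_hand(table) -> tuple[float, float, float]:
    """Loop-based balanced two-way moment estimators (truncated at zero)."""
    y = np.asarray(table, float)
    n, k = y.shape
    grand = y.sum() / (n * k)
    ss_case = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_scor = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_case = ss_case / (n - 1)
    ms_scor = ss_scor / (k - 1)
    ms_err = (ss_tot - ss_case - ss_scor) / ((n - 1) * (k - 1))
    return (
        max((ms_case - ms_err) / k, 0.0),
        max((ms_scor - ms_err) / n, 0.0),
        max(ms_err, 0.0),
    )
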