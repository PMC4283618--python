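"""Group-comparison and clinical-association tests.

Thin, validated wrappers around the standard nonparametric tests used in the
validation analysis, each returning a uniform :class:`AssociationResult`:
Pearson chi-square on r×c contingency tables (no continuity correction —
the published group comparisons are reproduced only without it), the
two-sided Fisher exact test for sparse 2×2 tables (point-probability
convention), Mann–Whitney U (exact for small untied samples, otherwise the
tie-corrected normal approximation without continuity correction), Kruskal–
Wallis, and Spearman rank correlation with its t-based test of independence
plus an optional seeded permutation p-value.  ``choose_test`` encodes the
"chi-square or Fisher, as appropriate" rule: Fisher for a 2×2 table with any
expected count below 5, chi-square otherwise.  Missing values are dropped
pairwise by the callers; no multiple-testing adjustment is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "pearson_chi2",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "kruskal_wallis",
    "spearman",
    "choose_test",
]


@dataclass(frozen=True)
class AssociationResult:
    test_name: str
    statistic: float
    p_value: float
    df: Optional[float] = None
    effect: Optional[float] = None  # Spearman r where applicable
    note: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


def _as_counts(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError(f"contingency table must be at least 2x2, got shape {t.shape}")
    if (t < 0).any() or t.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    return t


def pearson_chi2(table) -> AssociationResult:
    """Pearson chi-square test of homogeneity/independence, no continuity
    correction; df = (r-1)(c-1)."""
    t = _as_counts(table)
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError(
            "zero row/column marginal; collapse the empty category before testing"
        )
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return AssociationResult("pearson_chi2", float(chi2), float(p), df=float(df))


def fisher_exact_2x2(table) -> AssociationResult:
    """Two-sided Fisher exact test for a 2×2 table (point-probability method:
    the p-value sums hypergeometric probabilities no larger than the observed
    table's)."""
    t = _as_counts(table)
    if t.shape != (2, 2):
        raise ValueError(f"Fisher exact test requires a 2x2 table, got shape {t.shape}")
    odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return AssociationResult("fisher_exact", float(odds), float(p))


def mann_whitney_u(x, y) -> AssociationResult:
    """Two-sided Mann–Whitney U from mid-ranks.

    Exact null distribution when n_x + n_y <= 12 with no ties; otherwise the
    normal approximation with tie-corrected variance (no continuity
    correction, so that the two-group Kruskal–Wallis H equals z²).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 12 and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        note = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        note = "normal_approx_tie_corrected"
    return AssociationResult("mann_whitney_u", float(res.statistic), float(min(res.pvalue, 1.0)), note=note)


def kruskal_wallis(*groups) -> AssociationResult:
    """Kruskal–Wallis H on mid-ranks with tie correction; p from chi-square
    with k-1 df.  All-identical observations give H = 0, p = 1."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and np.ndim(groups[0][0]) > 0:
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return AssociationResult("kruskal_wallis", 0.0, 1.0, df=float(len(arrays) - 1))
    h, p = stats.kruskal(*arrays)
    return AssociationResult("kruskal_wallis", float(h), float(p), df=float(len(arrays) - 1))


def spearman(
    x,
    y,
    method: str = "t",
    n_perm: int = 5000,
    seed: int | None = 0,
) -> AssociationResult:
    """Spearman rank correlation with a test of independence.

    Pairs with a missing member are dropped (pairwise deletion); at least 3
    complete pairs are required.  ``method='t'`` uses the t approximation
    t = r*sqrt((n-2)/(1-r²)) on n-2 df; ``method='permutation'`` uses a
    seeded permutation of y.  Zero variance in either variable is flagged
    (r undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult("spearman", float("nan"), 1.0, df=float(n - 2),
                                 effect=None, note="zero_variance")
    r, p_t = stats.spearmanr(x, y)
    if method == "t":
        return AssociationResult("spearman", float(r), float(p_t), df=float(n - 2), effect=float(r))
    if method != "permutation":
        raise ValueError(f"method must be 't' or 'permutation', got {method!r}")
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = 0
    for _ in range(n_perm):
        hits += abs(np.corrcoef(rx, rng.permutation(ry))[0, 1]) >= obs - 1e-12
    p = (hits + 1) / (n_perm + 1)
    return AssociationResult(
        "spearman_permutation", float(r), float(p), df=float(n - 2), effect=float(r)
    )


def choose_test(table) -> str:
    """'fisher_exact_2x2' for a 2×2 table with any expected count < 5, else
    'pearson_chi2' (r×c tables always use chi-square)."""
    t = _as_counts(table)
    if t.shape == (2, 2):
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        if (expected < 5).any():
            return "fisher_exact_2x2"
    return "pearson_chi2"


def compare_groups(table) -> AssociationResult:
    """Apply the appropriate categorical test chosen by :func:`choose_test`."""
    name = choose_test(table)
    return fisher_exact_2x2(table) if name == "fisher_exact_2x2" else pearson_chi2(table)
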