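"""Inter- and intra-observer reliability statistics.

Ratings from a scoring exercise form a case × scorer table (possibly
incomplete for partial designs).  The working model is two-way random
effects without interaction,

    y_ij = mu + c_i + s_j + e_ij,

with independent zero-mean case, scorer and residual effects.  From the
estimated variance components this module derives

* the intraclass correlation coefficient (reliability), single-rater
  absolute-agreement form:  ICC = var_case / (var_case + var_scorer + var_error);
* the scorer-agreement ratio  alpha = sd_scorer / sd_case  (low alpha means
  scorers agree on the level of the scale);
* a good / good* / poor item classification (good: ICC > 0.6 and
  alpha < 0.4; good*: exactly one of the two; poor: neither);
* intra-observer proportional agreement pA (exact score matches between two
  reading sessions, per scorer and item).

Variance components come from the balanced two-way ANOVA moment estimators
on complete tables and from restricted maximum likelihood (REML) on
incomplete ones; negative moment estimates are truncated at zero, which is
why items scored identically by all scorers report ICC = 0 and alpha = 0.
Confidence intervals are nonparametric case-bootstrap percentile intervals
(cases resampled with replacement, each keeping all its ratings).

Ordinal scores are treated as numeric for variance estimation — standard
practice for a small number of ordered levels, and a documented limitation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

__all__ = [
    "VarianceComponents",
    "ReliabilityResult",
    "IntraraterResult",
    "estimate_variance_components",
    "icc",
    "alpha_score",
    "bootstrap_ci",
    "classify_item",
    "proportional_agreement",
    "InterRaterReliability",
    "reliability_table",
]

logger = logging.getLogger(__name__)

_EPS_DEGENERATE = 1e-12


@dataclass(frozen=True)
class VarianceComponents:
    var_case: float
    var_scorer: float
    var_error: float
    method: Literal["anova", "reml"] = "anova"
    degenerate: bool = False

    @property
    def total(self) -> float:
        return self.var_case + self.var_scorer + self.var_error


@dataclass(frozen=True)
class ReliabilityResult:
    item_id: str
    icc: float
    icc_ci: tuple[float, float] | None
    alpha: float
    alpha_ci: tuple[float, float] | None
    classification: str
    degenerate: bool
    components: VarianceComponents | None = None


@dataclass(frozen=True)
class IntraraterResult:
    """Per-item intra-observer agreement across scorers."""

    item_id: str
    pa_by_scorer: dict[str, float]
    median_pa: float
    range_pa: tuple[float, float]


# ---------------------------------------------------------------------------
# variance components


def _as_table(ratings) -> pd.DataFrame:
    """Coerce input to a case × scorer table with NaN for unobserved cells."""
    if isinstance(ratings, pd.DataFrame):
        if {"case_id", "scorer_id", "score"}.issubset(ratings.columns):
            return ratings.pivot_table(
                index="case_id", columns="scorer_id", values="score", aggfunc="mean"
            )
        return ratings.astype(float)
    return pd.DataFrame(np.asarray(ratings, dtype=float))


def _anova_components(values: np.ndarray) -> tuple[float, float, float]:
    """Balanced complete two-way moment estimators (one rating per cell)."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_case = k * np.sum((row_means - grand) ** 2)
    ss_scorer = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = max(ss_total - ss_case - ss_scorer, 0.0)
    ms_case = ss_case / (n - 1)
    ms_scorer = ss_scorer / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    var_error = ms_err
    var_scorer = max((ms_scorer - ms_err) / n, 0.0)
    var_case = max((ms_case - ms_err) / k, 0.0)
    return _snap_tiny(var_case, var_scorer, var_error)


def _snap_tiny(*components: float, rel: float = 1e-9) -> tuple[float, ...]:
    """Zero components that are numerically indistinguishable from 0 (floating
    cancellation in the sums of squares), relative to the total."""
    total = sum(components)
    return tuple(0.0 if v < rel * total else v for v in components)


def _reml_nll(params: np.ndarray, y: np.ndarray, zc: np.ndarray, zs: np.ndarray) -> float:
    vc, vs, ve = params
    n = y.size
    V = vc * (zc @ zc.T) + vs * (zs @ zs.T) + (ve + 1e-10) * np.eye(n)
    try:
        c, low = cho_factor(V, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    x = np.ones((n, 1))
    vi_x = cho_solve((c, low), x, check_finite=False)
    vi_y = cho_solve((c, low), y, check_finite=False)
    xtvix = (x.T @ vi_x).item()
    beta = (x.T @ vi_y).item() / xtvix
    r = y - beta
    quad = float(r @ cho_solve((c, low), r, check_finite=False))
    return 0.5 * (logdet_v + math.log(xtvix) + quad)


def _reml_components(table: pd.DataFrame) -> tuple[float, float, float]:
    """REML for the two-way crossed model on a possibly incomplete table.

    Maximises the restricted likelihood of V = var_case*Kc + var_scorer*Ks +
    var_error*I under non-negativity, starting from moment-style estimates;
    on balanced complete data the optimum coincides with the ANOVA
    estimators.
    """
    long = table.stack().reset_index()
    long.columns = ["case", "scorer", "y"]
    y = long["y"].to_numpy(float)
    zc = pd.get_dummies(long["case"]).to_numpy(float)
    zs = pd.get_dummies(long["scorer"]).to_numpy(float)

    scale = max(np.var(y), 1e-8)
    starts = [np.array([scale / 2, scale / 4, scale / 4])]
    complete = not table.isna().any().any()
    if complete and table.shape[0] >= 2 and table.shape[1] >= 2:
        starts.insert(0, np.array(_anova_components(table.to_numpy(float))) + 1e-12)

    best, best_val = None, np.inf
    bounds = [(0.0, None)] * 3
    for x0 in starts:
        res = optimize.minimize(
            _reml_nll,
            x0,
            args=(y, zc, zs),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    return _snap_tiny(*(max(v, 0.0) for v in best))


def estimate_variance_components(
    ratings, method: Literal["auto", "anova", "reml"] = "auto"
) -> VarianceComponents:
    """Estimate (var_case, var_scorer, var_error) from a ratings table.

    ``ratings`` is a case × scorer table (2-D array or wide DataFrame) or a
    long DataFrame with case_id/scorer_id/score columns.  Complete tables use
    the ANOVA moment estimators; incomplete tables use REML.  Requires at
    least two cases and two scorers.  An all-identical table yields
    (0, 0, 0) with the degenerate flag set.
    """
    table = _as_table(ratings)
    table = table.dropna(axis=0, how="all").dropna(axis=1, how="all")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 cases and 2 scorers, got {n} x {k}")
    values = table.to_numpy(float)
    observed = values[~np.isnan(values)]
    if observed.size == 0:
        raise ValueError("no ratings present")
    if np.ptp(observed) < _EPS_DEGENERATE:
        return VarianceComponents(0.0, 0.0, 0.0, method="anova", degenerate=True)

    complete = not np.isnan(values).any()
    if method == "anova" or (method == "auto" and complete):
        if not complete:
            raise ValueError("ANOVA estimators require a complete table; use method='reml'")
        vc, vs, ve = _anova_components(values)
        return VarianceComponents(vc, vs, ve, method="anova")
    vc, vs, ve = _reml_components(table)
    return VarianceComponents(vc, vs, ve, method="reml")


def icc(vc: VarianceComponents) -> float:
    """Single-rater absolute-agreement intraclass correlation."""
    total = vc.total
    if total <= 0:
        return 0.0
    return vc.var_case / total


def alpha_score(vc: VarianceComponents) -> float:
    """Scorer-agreement ratio sd_scorer / sd_case.

    Zero scorer variance gives 0 (perfect agreement on level) regardless of
    the case variance; zero case variance with positive scorer variance is
    reported as ``inf`` (the ratio is undefined upward).
    """
    if vc.var_scorer <= 0:
        return 0.0
    if vc.var_case <= 0:
        return float("inf")
    return math.sqrt(vc.var_scorer) / math.sqrt(vc.var_case)


def classify_item(icc_value: float, alpha_value: float) -> str:
    """good / good* / poor classification with strict thresholds.

    good: ICC > 0.6 and alpha < 0.4; good* (``"good_star"``): exactly one of
    the two; poor: neither.  Boundary values (ICC = 0.6, alpha = 0.4) do not
    count as high.
    """
    if not (0.0 <= icc_value <= 1.0):
        raise ValueError(f"icc must be in [0, 1], got {icc_value}")
    if not alpha_value >= 0.0:
        raise ValueError(f"alpha must be >= 0, got {alpha_value}")
    reliable = icc_value > 0.6
    agrees = alpha_value < 0.4
    if reliable and agrees:
        return "good"
    if reliable or agrees:
        return "good_star"
    return "poor"


def bootstrap_ci(
    ratings,
    statistic: Literal["icc", "alpha"] = "icc",
    B: int = 1000,
    seed: int | None = 0,
    method: Literal["auto", "anova", "reml"] = "auto",
) -> tuple[float, float]:
    """Percentile 95% CI by case resampling.

    Cases (rows) are drawn with replacement, each keeping all its ratings;
    resamples whose ratings are all identical or that retain fewer than two
    distinct cases are skipped (and counted in a debug log).  Deterministic
    under ``seed``.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    table = _as_table(ratings)
    table = table.dropna(axis=0, how="all").dropna(axis=1, how="all")
    n = table.shape[0]
    rng = np.random.default_rng(seed)
    stats: list[float] = []
    skipped = 0
    values = table.to_numpy(float)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) < 2:
            skipped += 1
            continue
        resampled = values[idx, :]
        obs = resampled[~np.isnan(resampled)]
        if obs.size == 0 or np.ptp(obs) < _EPS_DEGENERATE:
            skipped += 1
            continue
        try:
            vc = estimate_variance_components(pd.DataFrame(resampled), method=method)
        except ValueError:
            skipped += 1
            continue
        stats.append(icc(vc) if statistic == "icc" else alpha_score(vc))
    if skipped:
        logger.debug("bootstrap_ci: skipped %d degenerate resamples of %d", skipped, B)
    if not stats:
        return (0.0, 0.0)
    arr = np.asarray(stats, float)
    if np.isinf(arr).all():
        return (float("inf"), float("inf"))
    # nearest-order-statistic percentiles when infinities are present, to
    # avoid interpolating between an infinite and a finite resample
    method = "nearest" if np.isinf(arr).any() else "linear"
    lo, hi = np.percentile(arr, [2.5, 97.5], method=method)
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# intra-observer agreement


def proportional_agreement(session1: pd.DataFrame, session2: pd.DataFrame) -> dict[str, IntraraterResult]:
    """Exact-match proportional agreement between two reading sessions.

    Inputs are long DataFrames (scorer_id, case_id, item_id, score).  The two
    sessions must cover identical (scorer, case, item) triples; a mismatch
    raises with the missing pairs listed.  Returns, per item, pA for each
    scorer (matches / cases scored) with the median and range across scorers.
    """
    key = ["scorer_id", "case_id", "item_id"]
    s1 = session1[key + ["score"]].copy()
    s2 = session2[key + ["score"]].copy()
    k1 = set(map(tuple, s1[key].to_numpy()))
    k2 = set(map(tuple, s2[key].to_numpy()))
    if k1 != k2:
        missing = sorted(k1 ^ k2)[:20]
        raise ValueError(f"sessions cover different (scorer, case, item) triples, e.g. {missing}")
    merged = s1.merge(s2, on=key, suffixes=("_1", "_2"))
    merged["match"] = merged["score_1"] == merged["score_2"]
    out: dict[str, IntraraterResult] = {}
    for item_id, grp in merged.groupby("item_id", sort=False):
        pa = grp.groupby("scorer_id")["match"].mean()
        out[str(item_id)] = IntraraterResult(
            item_id=str(item_id),
            pa_by_scorer={str(k): float(v) for k, v in pa.items()},
            median_pa=float(pa.median()),
            range_pa=(float(pa.min()), float(pa.max())),
        )
    return out


# ---------------------------------------------------------------------------
# estimator interface


class InterRaterReliability(BaseEstimator):
    """Inter-observer reliability of one rated item, estimator-style.

    Fit on a case × scorer ratings table (wide DataFrame / 2-D array, NaN for
    unobserved cells) or a long DataFrame with case_id/scorer_id/score
    columns.  Fitted attributes: ``var_case_``, ``var_scorer_``,
    ``var_error_``, ``icc_``, ``alpha_``, ``classification_``,
    ``degenerate_`` and, when ``n_boot`` is set, ``icc_ci_`` / ``alpha_ci_``.

    Parameters
    ----------
    method : {'auto', 'anova', 'reml'}
        Variance-component estimator; 'auto' uses ANOVA on complete tables
        and REML otherwise.
    n_boot : int or None
        Number of case-bootstrap resamples for percentile CIs (None skips
        CIs).
    random_state : int
        Seed for the bootstrap.
    """

    def __init__(self, method: str = "auto", n_boot: int | None = 1000, random_state: int = 0):
        self.method = method
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None):
        vc = estimate_variance_components(X, method=self.method)
        self.components_ = vc
        self.var_case_ = vc.var_case
        self.var_scorer_ = vc.var_scorer
        self.var_error_ = vc.var_error
        self.degenerate_ = vc.degenerate
        self.icc_ = icc(vc)
        self.alpha_ = alpha_score(vc)
        self.classification_ = classify_item(self.icc_, self.alpha_)
        if self.n_boot:
            self.icc_ci_ = bootstrap_ci(X, "icc", B=self.n_boot, seed=self.random_state, method=self.method)
            self.alpha_ci_ = bootstrap_ci(X, "alpha", B=self.n_boot, seed=self.random_state, method=self.method)
        else:
            self.icc_ci_ = None
            self.alpha_ci_ = None
        return self

    def score(self, X=None, y=None) -> float:
        """Reliability (ICC) of the fitted table."""
        return self.icc_

    def to_result(self, item_id: str = "") -> ReliabilityResult:
        return ReliabilityResult(
            item_id=item_id,
            icc=self.icc_,
            icc_ci=self.icc_ci_,
            alpha=self.alpha_,
            alpha_ci=self.alpha_ci_,
            classification=self.classification_,
            degenerate=self.degenerate_,
            components=self.components_,
        )


def reliability_table(
    scores: pd.DataFrame,
    items: Sequence[str] | None = None,
    n_boot: int | None = 1000,
    seed: int = 0,
    method: str = "auto",
) -> pd.DataFrame:
    """Per-item reliability summary from a long scores DataFrame.

    Output columns: item_id, icc, icc_lo, icc_hi, alpha, alpha_lo, alpha_hi,
    class, degenerate.
    """
    item_ids = list(items) if items is not None else list(pd.unique(scores["item_id"]))
    rows = []
    for iid in item_ids:
        sub = scores[scores["item_id"] == iid]
        est = InterRaterReliability(method=method, n_boot=n_boot, random_state=seed).fit(sub)
        rows.append(
            {
                "item_id": iid,
                "icc": est.icc_,
                "icc_lo": est.icc_ci_[0] if est.icc_ci_ else np.nan,
                "icc_hi": est.icc_ci_[1] if est.icc_ci_ else np.nan,
                "alpha": est.alpha_,
                "alpha_lo": est.alpha_ci_[0] if est.alpha_ci_ else np.nan,
                "alpha_hi": est.alpha_ci_[1] if est.alpha_ci_ else np.nan,
                "class": est.classification_,
                "degenerate": est.degenerate_,
            }
        )
    return pd.DataFrame(rows)
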