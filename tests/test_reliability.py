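import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myoscore as ms
from myoscore.reliability import VarianceComponents

from .oracles import anova_components_by_hand


class TestVarianceComponents:
    def test_pure_case_signal(self):
        # every scorer gives case i the value i: no scorer or residual variance
        table = np.tile(np.arange(6, dtype=float)[:, None], (1, 4))
        vc = ms.estimate_variance_components(table)
        assert vc.var_scorer == 0.0
        assert vc.var_error == 0.0
        assert vc.var_case > 0.0

    def test_all_identical_is_degenerate(self):
        vc = ms.estimate_variance_components(np.ones((5, 5)))
        assert (vc.var_case, vc.var_scorer, vc.var_error) == (0.0, 0.0, 0.0)
        assert vc.degenerate

    def test_rejects_tiny_tables(self):
        with pytest.raises(ValueError, match="at least 2"):
            ms.estimate_variance_components(np.ones((1, 5)) * np.arange(5))

    def test_matches_loop_oracle(self, balanced_table):
        vc = ms.estimate_variance_components(balanced_table)
        oracle = anova_components_by_hand(balanced_table.to_numpy())
        assert vc.var_case == pytest.approx(oracle[0], rel=1e-10)
        assert vc.var_scorer == pytest.approx(oracle[1], rel=1e-10)
        assert vc.var_error == pytest.approx(oracle[2], rel=1e-10)

    def test_icc_matches_pingouin_two_way_random(self, balanced_table):
        pingouin = pytest.importorskip("pingouin")
        long = balanced_table.stack().reset_index()
        long.columns = ["case", "scorer", "y"]
        icc_tab = pingouin.intraclass_corr(
            data=long, targets="case", raters="scorer", ratings="y"
        ).set_index("Type")
        vc = ms.estimate_variance_components(balanced_table)
        # ICC(A,1): two-way random effects, absolute agreement, single rater
        assert ms.icc(vc) == pytest.approx(icc_tab.loc["ICC(A,1)", "ICC"], abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reml_equals_anova_on_balanced_data(self, seed):
        rng = np.random.default_rng(seed)
        y = (
            rng.normal(0, 1, 10)[:, None]
            + rng.normal(0, 0.4, 7)[None, :]
            + rng.normal(0, 0.6, (10, 7))
        )
        va = ms.estimate_variance_components(y, method="anova")
        vr = ms.estimate_variance_components(y, method="reml")
        for a, r in [(va.var_case, vr.var_case), (va.var_scorer, vr.var_scorer),
                     (va.var_error, vr.var_error)]:
            assert r == pytest.approx(a, rel=1e-6, abs=1e-9)

    def test_reml_matches_mixedlm_on_incomplete_data(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(7)
        theta = rng.normal(0, 1, 15)
        b = rng.normal(0, 0.5, 8)
        rows = [
            (f"c{i}", f"s{j}", theta[i] + b[j] + rng.normal(0, 0.6))
            for i in range(15)
            for j in range(8)
            if rng.random() < 0.7
        ]
        df = pd.DataFrame(rows, columns=["case_id", "scorer_id", "score"])
        vc = ms.estimate_variance_components(df)
        assert vc.method == "reml"
        df2 = df.copy()
        df2["g"] = 1
        fit = smf.mixedlm(
            "score ~ 1", df2, groups="g",
            vc_formula={"case": "0 + C(case_id)", "scorer": "0 + C(scorer_id)"},
        ).fit(reml=True, method="lbfgs")
        assert vc.var_case == pytest.approx(fit.vcomp[0], rel=2e-3, abs=1e-4)
        assert vc.var_scorer == pytest.approx(fit.vcomp[1], rel=2e-3, abs=1e-4)
        assert vc.var_error == pytest.approx(fit.scale, rel=2e-3, abs=1e-4)


class TestIccAlpha:
    @pytest.mark.parametrize(
        "components,expected",
        [((1.0, 0.0, 0.0), 1.0), ((0.0, 0.0, 1.0), 0.0), ((0.6, 0.1, 0.3), 0.6)],
    )
    def test_icc_values(self, components, expected):
        assert ms.icc(VarianceComponents(*components)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "components,expected",
        [
            ((0.5, 0.0, 0.2), 0.0),   # no scorer variance -> perfect agreement
            ((0.3, 0.3, 0.1), 1.0),
            ((0.64, 0.04, 0.1), 0.25),
        ],
    )
    def test_alpha_values(self, components, expected):
        assert ms.alpha_score(VarianceComponents(*components)) == pytest.approx(expected)

    def test_alpha_flagged_infinite_when_cases_flat(self):
        assert math.isinf(ms.alpha_score(VarianceComponents(0.0, 0.5, 0.1)))

    def test_degenerate_table_reports_zero_icc_and_alpha(self):
        vc = ms.estimate_variance_components(np.full((4, 4), 2.0))
        assert ms.icc(vc) == 0.0
        assert ms.alpha_score(vc) == 0.0


class TestClassification:
    @pytest.mark.parametrize(
        "icc_value,alpha_value,expected",
        [
            (0.72, 0.15, "good"),
            (0.58, 0.41, "poor"),
            (0.60, 0.50, "poor"),    # 0.60 is not > 0.6
            (0.58, 0.39, "good_star"),
            (0.66, 0.40, "good_star"),  # 0.40 is not < 0.4
            (0.0, 0.0, "good_star"),
        ],
    )
    def test_published_boundary_cases(self, icc_value, alpha_value, expected):
        assert ms.classify_item(icc_value, alpha_value) == expected

    @settings(deadline=None, max_examples=200)
    @given(
        icc_value=st.floats(0, 1, allow_nan=False),
        alpha_value=st.floats(0, 5, allow_nan=False),
    )
    def test_exhaustive_and_mutually_exclusive(self, icc_value, alpha_value):
        cls = ms.classify_item(icc_value, alpha_value)
        reliable = icc_value > 0.6
        agrees = alpha_value < 0.4
        expected = {(True, True): "good", (False, False): "poor"}.get(
            (reliable, agrees), "good_star"
        )
        assert cls == expected

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            ms.classify_item(1.2, 0.1)
        with pytest.raises(ValueError):
            ms.classify_item(0.5, -0.1)


class TestMonotonicity:
    def test_scorer_noise_degrades_icc_and_inflates_alpha(self):
        """With common case/residual draws, scaling up scorer bias must not
        raise mean ICC nor lower mean alpha (averaged over replicates)."""
        rng = np.random.default_rng(99)
        n, k, reps = 20, 8, 100
        stats = {s: {"icc": [], "alpha": []} for s in (0.2, 0.8)}
        for _ in range(reps):
            theta = rng.normal(0, 1, n)[:, None]
            b = rng.normal(0, 1, k)[None, :]
            e = rng.normal(0, 0.5, (n, k))
            for sigma_s in stats:
                vc = ms.estimate_variance_components(theta + sigma_s * b + e)
                stats[sigma_s]["icc"].append(ms.icc(vc))
                a = ms.alpha_score(vc)
                stats[sigma_s]["alpha"].append(a if math.isfinite(a) else 10.0)
        assert np.mean(stats[0.8]["icc"]) <= np.mean(stats[0.2]["icc"])
        assert np.mean(stats[0.8]["alpha"]) >= np.mean(stats[0.2]["alpha"])


class TestBootstrap:
    def test_deterministic_under_seed(self, balanced_table):
        a = ms.bootstrap_ci(balanced_table, "icc", B=300, seed=5)
        b = ms.bootstrap_ci(balanced_table, "icc", B=300, seed=5)
        assert a == b
        assert a[0] <= a[1]

    def test_zero_scorer_variance_gives_null_alpha_interval(self):
        table = np.tile(np.arange(8, dtype=float)[:, None], (1, 5))
        assert ms.bootstrap_ci(table, "alpha", B=200, seed=0) == (0.0, 0.0)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(12)
        for rep in range(10):
            y = (
                rng.normal(0, 1, 12)[:, None]
                + rng.normal(0, 0.3, 6)[None, :]
                + rng.normal(0, 0.5, (12, 6))
            )
            vc = ms.estimate_variance_components(y)
            lo, hi = ms.bootstrap_ci(y, "icc", B=300, seed=rep)
            assert lo - 1e-9 <= ms.icc(vc) <= hi + 1e-9

    def test_rejects_small_b(self, balanced_table):
        with pytest.raises(ValueError, match="B"):
            ms.bootstrap_ci(balanced_table, "icc", B=50)


class TestProportionalAgreement:
    @staticmethod
    def _session(scores):
        rows = []
        for scorer, per_case in scores.items():
            for case, val in per_case.items():
                rows.append((scorer, case, "item_a", val))
        return pd.DataFrame(rows, columns=["scorer_id", "case_id", "item_id", "score"])

    def test_identical_sessions_give_perfect_agreement(self):
        s = self._session({"s1": {f"c{i}": i % 3 for i in range(8)}})
        res = ms.proportional_agreement(s, s.copy())
        assert res["item_a"].median_pa == 1.0
        assert res["item_a"].range_pa == (1.0, 1.0)

    def test_two_of_eight_disagreements_give_075(self):
        base = {f"c{i}": 1 for i in range(8)}
        s1 = self._session({"s1": base})
        flipped = dict(base, c0=0, c1=2)
        s2 = self._session({"s1": flipped})
        res = ms.proportional_agreement(s1, s2)
        assert res["item_a"].pa_by_scorer["s1"] == pytest.approx(0.75)

    def test_mismatched_coverage_rejected(self):
        s1 = self._session({"s1": {"c1": 1, "c2": 0}})
        s2 = self._session({"s1": {"c1": 1}})
        with pytest.raises(ValueError, match="different"):
            ms.proportional_agreement(s1, s2)


class TestEstimatorInterface:
    def test_sklearn_contract(self, quad_item_scores):
        est = ms.InterRaterReliability(n_boot=None)
        params = est.get_params()
        assert set(params) == {"method", "n_boot", "random_state"}
        est.set_params(n_boot=200, random_state=3).fit(quad_item_scores)
        assert 0.0 <= est.icc_ <= 1.0
        assert est.alpha_ >= 0.0
        assert est.classification_ in ("good", "good_star", "poor")
        assert est.icc_ci_[0] <= est.icc_ci_[1]
        assert est.score() == est.icc_

    def test_clone_compatible(self, quad_item_scores):
        from sklearn.base import clone

        est = ms.InterRaterReliability(n_boot=None, random_state=1)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_reliability_table_layout(self, quad_item_scores):
        out = ms.reliability_table(quad_item_scores, n_boot=None)
        assert list(out.columns) == [
            "item_id", "icc", "icc_lo", "icc_hi",
            "alpha", "alpha_lo", "alpha_hi", "class", "degenerate",
        ]
        assert len(out) == 1
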