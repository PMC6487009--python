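import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ctbodycomp.stats import (
    StatsError,
    TwoByTwo,
    fit_logistic,
    format_p,
    format_percent,
    mann_whitney,
    roc_auc,
    summarize_cohort,
    two_by_two,
)

from helpers import exact_mwu_p, pair_count_auc


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        cmp = mann_whitney([1, 2, 3], [4, 5, 6])
        assert cmp.u == 0.0
        assert cmp.p == pytest.approx(0.1)
        assert cmp.method == "exact"

    def test_identical_groups_p_one(self):
        cmp = mann_whitney([5, 5, 5], [5, 5, 5])
        assert cmp.p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney([], [1, 2])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        # tie-free small samples hit the exact branch
        pooled = rng.permutation(np.arange(10, dtype=float))
        x, y = pooled[:4], pooled[4:9]
        cmp = mann_whitney(x, y)
        assert cmp.method == "exact"
        assert cmp.p == pytest.approx(exact_mwu_p(x, y), abs=1e-12)

    @given(
        x=st.lists(st.integers(0, 20), min_size=1, max_size=30),
        y=st.lists(st.integers(0, 20), min_size=1, max_size=30),
    )
    def test_u_conservation(self, x, y):
        u1 = mann_whitney(x, y).u
        u2 = mann_whitney(y, x).u
        assert u1 + u2 == pytest.approx(len(x) * len(y))
        assert 0 <= u1 <= len(x) * len(y)

    def test_large_sample_uses_tie_corrected_asymptotic(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(1, 6, 35).astype(float)
        cmp = mann_whitney(x, y)
        assert cmp.method == "asymptotic"
        assert 0 < cmp.p <= 1


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = [1] * 25 + [0] * 75
        fit = fit_logistic(y, pd.DataFrame(index=range(100)))
        assert fit.coef[0] == pytest.approx(math.log(25 / 75), abs=1e-6)
        assert fit.converged

    def test_single_binary_predictor_equals_cross_product_ratio(self):
        # 2x2 table: exposed 30 with 12 events, unexposed 50 with 8 events
        y = [1] * 12 + [0] * 18 + [1] * 8 + [0] * 42
        x = [1] * 30 + [0] * 50
        fit = fit_logistic(y, {"x": x})
        expected_or = (12 * 42) / (18 * 8)
        assert fit.odds_ratios[1] == pytest.approx(expected_or, rel=1e-6)

    def test_matches_statsmodels_on_random_data(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        n = 400
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.binomial(1, 0.4, n)})
        eta = -0.5 + 0.8 * X["a"] - 0.6 * X["b"]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        fit = fit_logistic(y.astype(int), X)
        ref = sm.Logit(y.astype(int), sm.add_constant(X)).fit(disp=0)
        assert fit.coef == pytest.approx(ref.params.values, abs=1e-6)
        assert fit.se == pytest.approx(ref.bse.values, rel=1e-4)

    def test_likelihood_monotone_and_gradient_small(self):
        rng = np.random.default_rng(11)
        n = 300
        X = pd.DataFrame({"a": rng.normal(size=n)})
        y = (rng.random(n) < 0.3).astype(int)
        fit = fit_logistic(y, X)
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) >= -1e-9)
        assert fit.max_grad < 1e-6

    def test_complete_separation_flagged_not_returned_as_stable(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        fit = fit_logistic(y, {"x": x})
        assert fit.separation
        assert not fit.converged

    def test_single_class_outcome_rejected(self):
        with pytest.raises(StatsError, match="single class"):
            fit_logistic([1, 1, 1, 1], {"x": [1, 2, 3, 4]})

    def test_wald_ci_brackets_odds_ratio(self):
        y = [1] * 12 + [0] * 18 + [1] * 8 + [0] * 42
        fit = fit_logistic(y, {"x": [1] * 30 + [0] * 50})
        ci = fit.conf_int()
        assert np.all(ci[:, 0] <= fit.odds_ratios)
        assert np.all(fit.odds_ratios <= ci[:, 1])


class TestRoc:
    def test_perfect_separation_auc_one(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_null_scores_auc_half(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=4000)
        y = rng.binomial(1, 0.4, 4000)
        assert roc_auc(s, y).auc == pytest.approx(0.5, abs=0.03)

    def test_orientation_flag_for_low_risk_markers(self):
        scores = [10, 20, 30, 1, 2, 3]
        labels = [0, 0, 0, 1, 1, 1]  # events have LOW scores
        assert roc_auc(scores, labels).auc == 0.0
        assert roc_auc(scores, labels, lower_is_positive=True).auc == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        s = rng.integers(0, 8, n).astype(float)  # heavy ties
        y = rng.binomial(1, 0.5, n)
        if len(set(y)) < 2:
            y[0] = 1 - y[0]
        r = roc_auc(s, y)
        assert r.auc == pytest.approx(pair_count_auc(s, y), abs=1e-12)

    def test_auc_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(8)
        s = rng.normal(size=200) + np.repeat([0, 1], 100)
        y = np.repeat([0, 1], 100)
        assert roc_auc(s, y).auc == pytest.approx(sk.roc_auc_score(y, s), abs=1e-12)

    def test_auc_u_identity_cross_module(self):
        rng = np.random.default_rng(13)
        s = rng.integers(0, 10, 80).astype(float)
        y = rng.binomial(1, 0.45, 80)
        r = roc_auc(s, y)
        cmp = mann_whitney(s[y == 1], s[y == 0])  # U of the event group
        assert r.auc == pytest.approx(cmp.u / (cmp.n1 * cmp.n2), abs=1e-12)

    def test_curve_monotone(self):
        rng = np.random.default_rng(17)
        s = rng.normal(size=100)
        y = rng.binomial(1, 0.3, 100)
        r = roc_auc(s, y)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(StatsError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestTwoByTwo:
    def test_printed_duct_percentages(self):
        t = TwoByTwo(23, 46, 14, 56)  # narrow-duct major complications
        assert t.row_percent_exposed() == "33.3"
        t2 = TwoByTwo(17, 52, 9, 61, percent_mode="truncate")
        assert t2.row_percent_unexposed() == "12.8"

    def test_odds_ratio_cross_product(self):
        t = TwoByTwo(28, 32, 9, 70)
        assert t.odds_ratio() == pytest.approx(1960 / 288)

    def test_haldane_anscombe_on_zero_cell(self):
        t = TwoByTwo(5, 0, 3, 7)
        assert t.odds_ratio() == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_percentages_rederive_from_counts(self):
        t = TwoByTwo(13, 17, 7, 23)
        assert t.row_percent_exposed() == format_percent(13, 30)
        assert t.row_percent_unexposed() == format_percent(7, 30)

    def test_predicate_tabulation_excludes_unmeasurable(self):
        from ctbodycomp.cohort import CohortSpec, generate_cohort

        recs = generate_cohort(CohortSpec(n_patients=80, seed=2))
        n_missing = sum(r.dpd is None for r in recs)
        t = two_by_two(
            recs,
            exposure=lambda r: None if r.dpd is None else r.dpd < 3.0,
            event=lambda r: r.severe_popf,
        )
        assert t.n_exposed + t.n_unexposed == len(recs) - n_missing


class TestFormatters:
    @pytest.mark.parametrize("count, total, mode, expect", [
        (139, 347, "half-up", "40.1"),
        (84, 139, "half-up", "60.4"),
        (23, 69, "half-up", "33.3"),
        (28, 37, "half-up", "75.7"),
        (22, 26, "half-up", "84.6"),
        (9, 70, "truncate", "12.8"),
        (23, 69, "truncate", "33.3"),
        (1, 3, "truncate", "33.3"),
    ])
    def test_one_decimal_modes(self, count, total, mode, expect):
        assert format_percent(count, total, mode) == expect

    def test_p_value_printed_as_upper_bound(self):
        assert format_p(0.032) == "p < 0.04"
        assert format_p(0.0099) == "p < 0.01"
        assert format_p(0.04) == "p < 0.04"


class TestSummarize:
    def _cohort(self, n=60, seed=4):
        from ctbodycomp.cohort import CohortSpec, generate_cohort

        return generate_cohort(CohortSpec(n_patients=n, seed=seed))

    def test_report_covers_both_endpoints_and_all_variables(self):
        table = summarize_cohort(self._cohort())
        assert set(table["endpoint"]) == {"major", "popf_severe"}
        assert "MA [HU]" in set(table["variable"])
        assert "sarcopenic [n]" in set(table["variable"])

    def test_deterministic_report(self):
        t1 = summarize_cohort(self._cohort())
        t2 = summarize_cohort(self._cohort())
        pd.testing.assert_frame_equal(t1, t2)

    def test_constructed_shift_shows_in_group_medians(self):
        # build records whose MA is clearly lower in the event group
        recs = self._cohort(n=120, seed=9)
        import dataclasses

        shifted = []
        for r in recs:
            comp = dataclasses.replace(r.composition, ma=20.0 if r.severe_popf else 45.0)
            r.composition = comp
            shifted.append(r)
        table = summarize_cohort(shifted)
        row = table[(table.endpoint == "popf_severe") & (table.variable == "MA [HU]")].iloc[0]
        assert row["median_event"] < row["median_noevent"]
        assert row["p"] < 0.001
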