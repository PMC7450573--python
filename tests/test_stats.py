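"""Odds ratios, chi-square, rank tests, logistic regression and ROC/AUC."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from renal_angina.stats import (
    ContingencyTable,
    auc_binary,
    auc_scores,
    chi_square_test,
    combined_predictor_auc,
    fit_logistic,
    odds_ratio_wald,
    rank_compare,
    t_compare,
    youden_cutoff,
)

cells = st.integers(min_value=1, max_value=40)


def brute_force_auc(scores, outcomes):
    """Case-control pairwise comparison oracle with ties counted one half."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, int)
    cases = scores[outcomes == 1]
    controls = scores[outcomes == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


class TestOddsRatio:
    def test_rai_table(self):
        r = odds_ratio_wald(ContingencyTable(30, 8, 6, 22))
        assert r.or_point == pytest.approx(13.75)
        assert r.ci_low == pytest.approx(4.17, abs=0.005)
        assert r.ci_high == pytest.approx(45.33, abs=0.005)
        assert r.p_value < 0.01

    def test_scr_table(self):
        r = odds_ratio_wald(ContingencyTable(28, 11, 8, 19))
        assert r.or_point == pytest.approx(6.045, abs=0.001)
        assert r.ci_high == pytest.approx(17.82, abs=0.005)

    def test_symmetric_table_is_one(self):
        r = odds_ratio_wald(ContingencyTable(10, 10, 10, 10))
        assert r.or_point == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_zero_cell_error_names_cell(self):
        with pytest.raises(ValueError, match="'b'"):
            odds_ratio_wald(ContingencyTable(5, 0, 3, 7))

    def test_haldane_correction_handles_zero(self):
        r = odds_ratio_wald(ContingencyTable(5, 0, 3, 7), haldane_correction=True)
        assert r.or_point == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_transposed_exposure_inverts_or_and_swaps_ci(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        fwd, rev = odds_ratio_wald(t), odds_ratio_wald(t.transpose_exposure())
        assert rev.or_point == pytest.approx(1 / fwd.or_point)
        assert rev.ci_low == pytest.approx(1 / fwd.ci_high)
        assert rev.ci_high == pytest.approx(1 / fwd.ci_low)


class TestChiSquare:
    def test_independence_gives_zero(self):
        r = chi_square_test(ContingencyTable(10, 10, 10, 10))
        assert r.statistic == pytest.approx(0.0) and r.p_value == pytest.approx(1.0)

    def test_rai_table_statistic(self):
        # n(ad-bc)^2 / (row and column margin product) = 21.51
        r = chi_square_test(ContingencyTable(30, 8, 6, 22))
        assert r.method == "pearson"
        assert r.statistic == pytest.approx(21.51, abs=0.005)

    def test_small_expected_counts_use_fisher(self):
        # expected count for cell a is 8*10/24 = 3.33 < 5
        r = chi_square_test(ContingencyTable(1, 7, 9, 7))
        assert r.method == "fisher"
        _, p = sps.fisher_exact([[1, 7], [9, 7]])
        assert r.p_value == pytest.approx(p)

    def test_expected_exactly_five_stays_pearson(self):
        # 1/9 vs 9/1 has every expected count exactly 5; the fallback rule
        # is strict (< 5)
        assert chi_square_test(ContingencyTable(1, 9, 9, 1)).method == "pearson"

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test(ContingencyTable(0, 0, 5, 5))


class TestGroupCompare:
    def test_identical_groups_p_one(self, caplog):
        with caplog.at_level("WARNING"):
            r = rank_compare([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r.p_value == 1.0

    def test_separated_groups_minimal_asymptotic_p(self):
        """{1,2,3} vs {10,11,12}: U = 0 and the p-value equals the minimum
        over all 20 relabelings (exhaustive permutation oracle)."""
        r = rank_compare([1, 2, 3], [10, 11, 12])
        assert r.statistic == 0.0
        pool = [1, 2, 3, 10, 11, 12]
        ps = []
        for combo in itertools.combinations(range(6), 3):
            g0 = [pool[i] for i in combo]
            g1 = [pool[i] for i in range(6) if i not in combo]
            ps.append(rank_compare(g0, g1).p_value)
        assert r.p_value == pytest.approx(min(ps))

    def test_agrees_with_scipy_midrank_normal_approximation(self):
        rng = np.random.default_rng(0)
        g0 = np.round(rng.gamma(2, 2, 25), 1)  # ties via rounding
        g1 = np.round(rng.gamma(2.5, 2, 30), 1)
        r = rank_compare(g0, g1)
        ref = sps.mannwhitneyu(g0, g1, alternative="two-sided", method="asymptotic")
        assert r.p_value == pytest.approx(float(ref.pvalue))

    def test_lactate_like_split_detected(self):
        rng = np.random.default_rng(42)
        non = rng.lognormal(math.log(2.8), 0.63, 30)
        sev = rng.lognormal(math.log(4.0), 0.87, 36)
        assert rank_compare(non, sev).p_value < 0.05

    def test_t_compare_matches_scipy(self):
        g0, g1 = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0]
        r = t_compare(g0, g1)
        stat, p = sps.ttest_ind(g0, g1)
        assert (r.statistic, r.p_value) == (pytest.approx(float(stat)), pytest.approx(float(p)))


class TestLogistic:
    def test_saturated_binary_model_matches_closed_form_or(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 40, size=4)
            x = np.r_[np.ones(a + b), np.zeros(c + d)]
            y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
            fit = fit_logistic(y, x)
            assert fit.converged
            closed = odds_ratio_wald(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert math.exp(fit.params[1]) == pytest.approx(closed.or_point, abs=1e-6)

    def test_independent_covariate_slope_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y = rng.integers(0, 2, size=500)
        fit = fit_logistic(y, x)
        assert abs(fit.params[1]) < 0.2

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        p = 1 / (1 + np.exp(-(0.5 + X @ [1.0, -0.7])))
        y = (rng.random(200) < p).astype(float)
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.params == pytest.approx(ref.params, abs=1e-6)
        assert fit.se == pytest.approx(ref.bse, rel=1e-4)

    def test_separation_is_flagged_not_silent(self, caplog):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        with caplog.at_level("WARNING"):
            fit = fit_logistic(y, x)
        assert not fit.converged
        assert fit.diagnostic
        assert "flagged" in caplog.text

    def test_collinear_design_rejected(self):
        x = np.ones((20, 2))
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(np.r_[np.zeros(10), np.ones(10)], x)


class TestROC:
    def test_binary_rai_table(self):
        r = auc_binary(ContingencyTable(30, 8, 6, 22))
        assert r.auc == pytest.approx((30 / 36 + 22 / 30) / 2)
        assert r.curve_points[1] == (pytest.approx(8 / 30), pytest.approx(30 / 36))

    def test_binary_useless_test(self):
        assert auc_binary(ContingencyTable(5, 5, 5, 5)).auc == pytest.approx(0.5)

    def test_binary_zero_outcome_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            auc_binary(ContingencyTable(0, 5, 0, 5))

    @pytest.mark.parametrize(
        "scores,outcomes,expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),
            ([1, 1, 2, 2], [0, 1, 0, 1], 0.5),  # ties count one half
        ],
    )
    def test_small_examples(self, scores, outcomes, expected):
        assert auc_scores(scores, outcomes).auc == pytest.approx(expected)

    def test_matches_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(500):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.normal(size=n), 1)
            outcomes = np.zeros(n, int)
            outcomes[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if outcomes.sum() in (0, n):
                continue
            r = auc_scores(scores, outcomes)
            assert r.auc == pytest.approx(brute_force_auc(scores, outcomes), abs=1e-12)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        scores = rng.normal(size=300)
        outcomes = (rng.random(300) < 1 / (1 + np.exp(-scores))).astype(int)
        assert auc_scores(scores, outcomes).auc == pytest.approx(
            float(sk.roc_auc_score(outcomes, scores))
        )

    def test_binary_scores_reproduce_auc_binary_exactly(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 30, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            scores = np.r_[np.ones(a + b), np.zeros(c + d)]
            outcomes = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)].astype(int)
            assert auc_scores(scores, outcomes).auc == pytest.approx(auc_binary(t).auc, abs=1e-12)

    @given(
        shift=st.floats(min_value=-5, max_value=5),
        scale=st.floats(min_value=0.01, max_value=10),
    )
    def test_invariant_under_monotone_transform(self, shift, scale):
        scores = np.array([0.1, 0.4, 0.2, 0.9, 0.5, 0.7])
        outcomes = np.array([0, 0, 0, 1, 1, 1])
        base = auc_scores(scores, outcomes).auc
        assert auc_scores(scores * scale + shift, outcomes).auc == pytest.approx(base)
        assert auc_scores(np.exp(scores), outcomes).auc == pytest.approx(base)

    def test_constant_scores_auc_half_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            r = auc_scores([1.0, 1.0, 1.0], [0, 1, 1])
        assert r.auc == 0.5

    def test_curve_coordinates_monotone(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=60)
        outcomes = (rng.random(60) < 0.4).astype(int)
        pts = auc_scores(scores, outcomes).curve_points
        xs, ys = zip(*pts)
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        assert all(np.diff(xs) >= 0) and all(np.diff(ys) >= 0)


class TestCombined:
    def test_constant_lactate_degenerates_to_binary_auc(self):
        rng = np.random.default_rng(8)
        flags = rng.random(80) < 0.5
        outcomes = (rng.random(80) < np.where(flags, 0.7, 0.3)).astype(int)
        lact = np.full(80, 3.0)
        t = ContingencyTable.from_flags(flags, outcomes.astype(bool))
        roc = combined_predictor_auc(flags, lact, outcomes)
        assert roc.auc == pytest.approx(auc_binary(t).auc, abs=1e-9)

    def test_combined_dominates_single_predictors(self):
        """Data generated under the combined model class: the two-variable
        score cannot do worse than either single predictor (beyond MC noise)."""
        rng = np.random.default_rng(9)
        n = 4000
        flags = rng.random(n) < 0.55
        lact = rng.lognormal(1.1, 0.7, n)
        logit = -3.0 + 2.0 * flags + 0.3 * lact
        outcomes = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        combined = combined_predictor_auc(flags, lact, outcomes).auc
        single_rai = auc_binary(ContingencyTable.from_flags(flags, outcomes.astype(bool))).auc
        single_lact = auc_scores(lact, outcomes).auc
        assert combined >= max(single_rai, single_lact) - 0.01


class TestYouden:
    def test_exhaustive_scan_example(self):
        r = youden_cutoff([1, 2, 3, 4, 5], [0, 0, 1, 1, 1])
        assert r.threshold == 3.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_perfect_separation_returns_upper_gap_boundary(self):
        r = youden_cutoff([1.0, 2.0, 7.0, 9.0], [0, 0, 1, 1])
        assert r.threshold == 7.0 and r.youden_j == pytest.approx(1.0)

    def test_ties_break_toward_higher_threshold(self):
        # thresholds 3 and 4 both give J = 0.5; the higher one is returned
        r = youden_cutoff([1, 2, 3, 4], [0, 1, 0, 1])
        assert r.threshold == 4.0
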