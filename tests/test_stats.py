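import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from strokeclass import (
    TwoByTwo,
    chi2_rxc,
    confusion,
    diagnostic_metrics,
    mcnemar,
    odds_ratio,
    percent,
    round_half_up,
    welch_t,
    welch_t_from_summary,
    wilcoxon_ranksum,
    wilson_interval,
)

counts = st.integers(min_value=0, max_value=500)
pos_counts = st.integers(min_value=1, max_value=500)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(74.55, 74.6), (74.549, 74.5), (30.04, 30.0), (0.05, 0.1), (69.25, 69.3)],
    )
    def test_half_up_one_decimal(self, value, expected):
        assert round_half_up(value) == expected

    def test_percent_combines_scaling_and_rounding(self):
        assert percent(138 / 253) == 54.5


class TestConfusion:
    def test_perfect_prediction_has_no_off_diagonals(self):
        t = confusion([True, False, True], [True, False, True])
        assert (t.fp, t.fn) == (0, 0)

    def test_all_false_predictions(self):
        t = confusion([False] * 4, [True, False, True, False])
        assert (t.tp, t.fp) == (0, 0) and (t.fn, t.tn) == (2, 2)

    def test_published_basis_counts_from_vectors(self):
        """151 of 253 poor are BASIS-major, 249 BASIS-major total, n=649."""
        pred = [True] * 151 + [False] * 102 + [True] * 98 + [False] * 298
        poor = [True] * 253 + [False] * 396
        assert confusion(pred, poor) == TwoByTwo(151, 98, 102, 298)

    @pytest.mark.parametrize("bad", [([], []), ([True], [True, False])])
    def test_empty_or_mismatched_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            confusion(*bad)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 0, 0, 0)


class TestDiagnosticMetrics:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (TwoByTwo(151, 98, 102, 298), dict(sensitivity=59.7, specificity=75.3, ppv=60.6, npv=74.5, accuracy=69.2)),
            (TwoByTwo(138, 50, 115, 346), dict(sensitivity=54.5, specificity=87.4, ppv=73.4, npv=75.1, accuracy=74.6)),
        ],
    )
    def test_published_instrument_rows(self, table, expected):
        assert diagnostic_metrics(table).rounded_percents() == expected

    def test_perfect_table_scores_100_everywhere(self):
        m = diagnostic_metrics(TwoByTwo(5, 0, 0, 7)).rounded_percents()
        assert set(m.values()) == {100.0}

    def test_zero_denominator_flags_undefined_instead_of_raising(self):
        m = diagnostic_metrics(TwoByTwo(0, 3, 0, 7))
        assert not m.sensitivity.defined and math.isnan(m.sensitivity.estimate)
        assert m.specificity.defined

    @given(tp=counts, fp=counts, fn=counts, tn=counts)
    @settings(derandomize=True, max_examples=200)
    def test_accuracy_identity(self, tp, fp, fn, tn):
        t = TwoByTwo(tp, fp, fn, tn)
        if t.n == 0 or t.tp + t.fn == 0 or t.tn + t.fp == 0:
            return
        m = diagnostic_metrics(t)
        prev = m.prevalence
        acc = prev * m.sensitivity.estimate + (1 - prev) * m.specificity.estimate
        assert acc == pytest.approx(m.accuracy.estimate, abs=1e-12)

    def test_wilson_interval_matches_closed_form_case(self):
        # k=5, n=10, z=1.96: classic textbook Wilson bounds
        lo, hi = wilson_interval(5, 10)
        assert lo == pytest.approx(0.2366, abs=2e-4)
        assert hi == pytest.approx(0.7634, abs=2e-4)

    @given(k=st.integers(0, 100), n=st.integers(1, 100))
    @settings(derandomize=True, max_examples=100)
    def test_wilson_interval_brackets_estimate(self, k, n):
        if k > n:
            return
        lo, hi = wilson_interval(k, n)
        assert 0 <= lo <= k / n <= hi <= 1


class TestMcNemar:
    def test_symmetric_discordants_give_p_one(self):
        assert mcnemar(5, 5).p_value == 1.0

    def test_one_sided_extreme_exact_tail(self):
        res = mcnemar(10, 0)
        assert res.method == "mcnemar-exact"
        assert res.p_value == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_large_sample_continuity_corrected_chi2(self):
        res = mcnemar(40, 20)
        assert res.method == "mcnemar-chi2-cc"
        assert res.statistic == pytest.approx((abs(40 - 20) - 1) ** 2 / 60)
        assert res.p_value == pytest.approx(float(sps.chi2.sf(19**2 / 60, 1)), rel=1e-12)

    def test_no_discordant_pairs_degenerate(self):
        res = mcnemar(0, 0)
        assert res.degenerate and res.p_value == 1.0

    def test_exact_branch_equals_rational_binomial_enumeration(self):
        """Doubled-smaller-tail p agrees with exact Fraction arithmetic for
        every discordant split up to the branch threshold."""
        for n in range(1, 26):
            for b in range(n + 1):
                c = n - b
                k = min(b, c)
                tail = Fraction(sum(math.comb(n, i) for i in range(k + 1)), 2**n)
                expected = float(min(Fraction(1), 2 * tail))
                assert mcnemar(b, c).p_value == pytest.approx(expected, rel=1e-12), (b, c)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        res = mcnemar(12, 4)
        ref = sm_mcnemar([[0, 12], [4, 0]], exact=True)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-10)


class TestOddsRatio:
    def test_published_combined_instrument_or(self):
        r = odds_ratio(TwoByTwo(114, 33, 77, 281))
        assert round_half_up(r.estimate) == 12.6
        assert round_half_up(r.ci_low) == 7.9
        assert round_half_up(r.ci_high) == 20.0

    def test_balanced_table_is_null(self):
        assert odds_ratio(TwoByTwo(7, 7, 7, 7)).estimate == pytest.approx(1.0)

    def test_zero_cell_uses_haldane_correction(self):
        r = odds_ratio(TwoByTwo(5, 0, 3, 7))
        assert r.continuity_corrected
        assert r.estimate == pytest.approx((5.5 * 7.5) / (0.5 * 3.5), rel=1e-12)
        assert r.log_se == pytest.approx(
            math.sqrt(1 / 5.5 + 1 / 0.5 + 1 / 3.5 + 1 / 7.5), rel=1e-12
        )

    @given(a=pos_counts, b=pos_counts, c=pos_counts, d=pos_counts)
    @settings(derandomize=True, max_examples=200)
    def test_row_swap_inverts_or(self, a, b, c, d):
        t = TwoByTwo(a, b, c, d)
        prod = odds_ratio(t).estimate * odds_ratio(t.swap_rows()).estimate
        assert prod == pytest.approx(1.0, rel=1e-9)

    @given(a=pos_counts, b=pos_counts, c=pos_counts, d=pos_counts, m=st.integers(2, 9))
    @settings(derandomize=True, max_examples=200)
    def test_or_invariant_to_row_scaling(self, a, b, c, d, m):
        t = TwoByTwo(a, b, c, d)
        scaled = TwoByTwo(a * m, b * m, c, d)
        assert odds_ratio(scaled).estimate == pytest.approx(odds_ratio(t).estimate, rel=1e-9)

    def test_ci_brackets_estimate(self):
        r = odds_ratio(TwoByTwo(20, 10, 5, 40))
        assert r.ci_low <= r.estimate <= r.ci_high


class TestChi2:
    def test_identical_rows_give_zero_statistic(self):
        res = chi2_rxc([[10, 20, 30], [10, 20, 30]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_definitional_sum_on_2x3(self):
        obs = np.array([[12, 5, 9], [3, 14, 8]], dtype=float)
        rows, cols = obs.sum(1), obs.sum(0)
        exp = np.outer(rows, cols) / obs.sum()
        brute = sum(
            (obs[i, j] - exp[i, j]) ** 2 / exp[i, j] for i in range(2) for j in range(3)
        )
        res = chi2_rxc(obs)
        assert res.statistic == pytest.approx(brute, rel=1e-12)
        assert res.df == 2

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            obs = rng.integers(1, 15, size=(rng.integers(2, 4), rng.integers(2, 4)))
            res = chi2_rxc(obs)
            ref = sps.chi2_contingency(obs, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_yates_matches_scipy_2x2(self):
        obs = [[12, 5], [3, 14]]
        res = chi2_rxc(obs, yates=True)
        ref = sps.chi2_contingency(np.array(obs), correction=True)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_combined_stratification_is_highly_significant(self):
        # the published 3x2 poor/good by combined class
        res = chi2_rxc([[114, 33], [62, 82], [77, 281]])
        assert res.df == 2
        assert res.p_value < 1e-4

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_rxc([[0, 0], [3, 4]])


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        res = wilcoxon_ranksum([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_statistic_is_rank_sum_of_first_sample(self):
        res = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert res.statistic == 6.0  # ranks 1+2+3

    def test_null_moments_match_exhaustive_enumeration(self):
        """The normal approximation centres on the exact permutation mean and
        uses the exact tie-corrected permutation variance."""
        pooled = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0]
        n1 = 4
        ranks = sps.rankdata(pooled)
        sums = [sum(ranks[list(idx)]) for idx in itertools.combinations(range(8), n1)]
        exact_mean, exact_var = np.mean(sums), np.var(sums)
        x, y = pooled[:n1], pooled[n1:]
        res = wilcoxon_ranksum(x, y)
        z = (res.statistic - exact_mean) / math.sqrt(exact_var)
        assert res.p_value == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-12)

    def test_all_ties_degenerate(self):
        res = wilcoxon_ranksum([2, 2], [2, 2, 2])
        assert res.degenerate and res.p_value == 1.0

    def test_agrees_with_scipy_large_sample(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.5, 1, 80)
        res = wilcoxon_ranksum(x, y)
        ref = sps.ranksums(x, y)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestWelch:
    def test_identical_groups_give_zero_statistic(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_reduces_to_pooled_t_for_equal_n_equal_variance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 4.0, 5.0])
        res = welch_t(x, y)
        sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2
        pooled_t = (x.mean() - y.mean()) / math.sqrt(sp2 * (2 / 4))
        assert res.statistic == pytest.approx(pooled_t, rel=1e-12)
        assert res.df == pytest.approx(6.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 25), rng.normal(0.7, 2, 40)
        res = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_published_age_comparison_from_summaries(self):
        # age in ASPECTS-major vs ASPECTS-minor: 65.9+/-18.3 (121) vs 68.8+/-14.7 (528)
        res = welch_t_from_summary(65.9, 18.3, 121, 68.8, 14.7, 528)
        assert round(res.p_value, 2) == 0.11

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1.0, 0.0, 5, 1.0, 0.0, 5)
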