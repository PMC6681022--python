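import math
from datetime import date

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from chipseek.classify import ClassificationTable, HitCategory
from chipseek.stats import (
    TwoByTwo,
    age_days,
    chisq_2x2,
    compare_category_proportions,
    compliance_fraction,
    extrapolate_events,
    fleiss_sample_size,
    log_t_test,
    ppv,
    summarize_ages,
)


def chisq_oracle(a, b, c, d, yates=True):
    """Textbook oracle: expected counts written out longhand per cell."""
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    total = 0.0
    for obs, e in [
        (a, r1 * c1 / n),
        (b, r1 * c2 / n),
        (c, r2 * c1 / n),
        (d, r2 * c2 / n),
    ]:
        dev = abs(obs - e)
        if yates:
            dev = max(dev - 0.5, 0.0)
        total += dev * dev / e
    return total


class TestPPV:
    @pytest.mark.parametrize(
        "tp, n, expected", [(257, 1000, 0.257), (155, 1000, 0.155), (0, 50, 0.0)]
    )
    def test_exact_fraction(self, tp, n, expected):
        assert ppv(tp, n) == expected

    def test_zero_hits_rejected(self):
        with pytest.raises(ValueError):
            ppv(0, 0)


class TestChiSq2x2:
    @pytest.mark.parametrize(
        "table, expected, ndigits",
        [
            ((257, 743, 155, 845), 31.184, 3),
            ((11, 246, 36, 119), 32.49, 2),
            ((458, 542, 385, 615), 10.63, 2),
            ((203, 797, 164, 836), 4.819, 3),
        ],
    )
    def test_reproduces_reference_statistics(self, table, expected, ndigits):
        result = chisq_2x2(TwoByTwo(*table))
        assert round(result.statistic, ndigits) == expected
        assert result.yates and result.df == 1

    def test_identical_proportions_give_zero(self):
        assert chisq_2x2(TwoByTwo(10, 10, 10, 10)).statistic == 0.0

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2(TwoByTwo(0, 0, 5, 5))

    def test_oracle_equivalence_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 500, size=4)
            for yates in (True, False):
                got = chisq_2x2(TwoByTwo(int(a), int(b), int(c), int(d)), yates=yates)
                assert math.isclose(
                    got.statistic, chisq_oracle(a, b, c, d, yates), abs_tol=1e-9
                )

    def test_yates_never_exceeds_uncorrected_and_swap_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 200, size=4))
            corrected = chisq_2x2(TwoByTwo(a, b, c, d)).statistic
            plain = chisq_2x2(TwoByTwo(a, b, c, d), yates=False).statistic
            assert corrected <= plain + 1e-12
            # invariant under simultaneous row and column swaps
            swapped = chisq_2x2(TwoByTwo(d, c, b, a)).statistic
            assert math.isclose(corrected, swapped, rel_tol=1e-12)

    def test_agrees_with_scipy_away_from_floor(self):
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 50:
            a, b, c, d = (int(x) for x in rng.integers(5, 300, size=4))
            obs = np.array([[a, b], [c, d]], dtype=float)
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            if np.abs(obs - expected).min() < 0.5:
                continue  # scipy's correction differs only inside the floor
            res = chi2_contingency(obs, correction=True)
            got = chisq_2x2(TwoByTwo(a, b, c, d))
            assert math.isclose(got.statistic, res.statistic, rel_tol=1e-12)
            assert math.isclose(got.p_value, res.pvalue, rel_tol=1e-12)
            checked += 1


class TestCategoryComparison:
    @staticmethod
    def _tables():
        valid = ClassificationTable(
            {
                HitCategory.IMPLANTATION_EVENT: 257,
                HitCategory.BLANK_PREPOPULATED_FORM: 458,
                HitCategory.ABSENCE_NOTED: 5,
                HitCategory.TECHNICAL_PROBLEM: 1,
                HitCategory.NONE_OF_THE_ABOVE: 279,
            },
            total=1000,
        )
        invalid = ClassificationTable(
            {
                HitCategory.IMPLANTATION_EVENT: 155,
                HitCategory.BLANK_PREPOPULATED_FORM: 385,
                HitCategory.ABSENCE_NOTED: 87,
                HitCategory.TECHNICAL_PROBLEM: 1,
                HitCategory.NONE_OF_THE_ABOVE: 372,
            },
            total=1000,
        )
        return valid, invalid

    def test_full_sample_denominators_reproduce_statistics(self):
        valid, invalid = self._tables()
        rows = {r.category: r for r in compare_category_proportions(valid, invalid)}
        assert round(rows[HitCategory.BLANK_PREPOPULATED_FORM].chisq.statistic, 2) == 10.63
        assert round(rows[HitCategory.ABSENCE_NOTED].chisq.statistic, 3) == 74.754

    def test_percentages_use_false_positive_denominators(self):
        valid, invalid = self._tables()
        rows = {r.category: r for r in compare_category_proportions(valid, invalid)}
        blank = rows[HitCategory.BLANK_PREPOPULATED_FORM]
        assert math.isclose(blank.pct_valid, 100 * 458 / 743)
        assert math.isclose(blank.pct_invalid, 100 * 385 / 845)

    def test_infrequent_categories_flagged_not_tested(self):
        valid, invalid = self._tables()
        rows = {r.category: r for r in compare_category_proportions(valid, invalid)}
        rare = rows[HitCategory.TECHNICAL_PROBLEM]
        assert rare.chisq is None and rare.note == "too infrequent"
        assert HitCategory.IMPLANTATION_EVENT not in rows


class TestFleissSampleSize:
    def test_reference_scenario(self):
        spec = fleiss_sample_size(0.09, 0.19, power=0.80, confidence=0.95)
        assert spec.n_per_group == 208
        assert 187 < spec.n_uncorrected < 188

    def test_symmetric_in_proportions(self):
        a = fleiss_sample_size(0.09, 0.19)
        b = fleiss_sample_size(0.19, 0.09)
        assert a.n_per_group == b.n_per_group

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError):
            fleiss_sample_size(0.1, 0.1)


class TestAges:
    @pytest.mark.parametrize(
        "dob, event, expected",
        [
            (date(2017, 1, 1), date(2017, 3, 16), 74),
            (date(2017, 1, 1), date(2017, 1, 1), 0),
        ],
    )
    def test_age_days(self, dob, event, expected):
        assert age_days(dob, event) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            age_days(date(2017, 3, 16), date(2017, 1, 1))

    def test_summary_linear_interpolation_convention(self):
        s = summarize_ages([1, 2, 3, 4, 5])
        assert (s.median_days, s.iqr_days, s.n) == (3.0, 2.0, 5)
        single = summarize_ages([42])
        assert (single.median_days, single.iqr_days) == (42.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_ages([])


class TestLogTTest:
    def test_identical_groups_give_zero(self):
        res = log_t_test([3, 5, 8, 13], [3, 5, 8, 13])
        assert res.t_statistic == 0.0

    def test_swapping_groups_flips_sign(self):
        a, b = [2.0, 4.0, 9.0], [5.0, 7.0, 11.0]
        assert math.isclose(
            log_t_test(a, b).t_statistic, -log_t_test(b, a).t_statistic
        )

    def test_matches_hand_computed_closed_form(self):
        # In log-2 units the groups are {1,2,3,4} and {2,3,4,5}: equal
        # variances 5/3, mean difference -1, so t = -1 / sqrt(5/6).
        res = log_t_test([2, 4, 8, 16], [4, 8, 16, 32])
        assert math.isclose(res.t_statistic, -1 / math.sqrt(5 / 6), rel_tol=1e-12)

    def test_scale_invariance(self):
        a, b = [3, 6, 12], [4, 9, 20]
        t1 = log_t_test(a, b).t_statistic
        t2 = log_t_test([7 * x for x in a], [7 * x for x in b]).t_statistic
        assert math.isclose(t1, t2, rel_tol=1e-12)

    def test_zero_age_shift_recorded(self):
        res = log_t_test([0, 2, 3], [1, 2, 4])
        assert res.zeros_shifted

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            log_t_test([1], [2, 3])


class TestExtrapolationAndCompliance:
    def test_reference_extrapolation(self):
        ext = extrapolate_events(43_365, 0.257)
        assert math.isclose(ext.exact, 11144.805)
        assert ext.rounded == 11_000

    @pytest.mark.parametrize("p, expected", [(0.0, 0.0), (1.0, 500.0)])
    def test_boundary_ppv(self, p, expected):
        assert extrapolate_events(500, p).exact == expected

    def test_monotone_in_both_arguments(self):
        assert extrapolate_events(100, 0.3).exact < extrapolate_events(200, 0.3).exact
        assert extrapolate_events(100, 0.3).exact < extrapolate_events(100, 0.4).exact

    def test_compliance_fraction(self):
        assert compliance_fraction([10, 80, 100], 84) == pytest.approx(2 / 3)
        assert compliance_fraction([100, 120], 84) == 0.0
        assert compliance_fraction([84], 84) == 1.0
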