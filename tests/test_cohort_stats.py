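"""Statistics: summaries, paired differences, Wilcoxon, normality, Spearman."""

import itertools

import numpy as np
import pytest
from scipy import stats

from brainshift.cohort_stats import (
    DegenerateDataError,
    analyze_cohort,
    dagostino_pearson,
    paired_differences,
    spearman,
    summarize,
    wilcoxon_signed_rank,
)
from brainshift.mask_io import load_reference_cohort


def brute_force_wilcoxon_exact_p(diffs):
    """Literal enumeration of all 2^n sign assignments (no-tie case)."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    n = len(d)
    w_plus = ranks[d > 0].sum()
    w_obs = min(w_plus, ranks[d < 0].sum())
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.asarray(signs, dtype=bool)].sum()
        if w <= w_obs:
            count += 1
    return min(1.0, 2.0 * count / 2**n)


class TestSummarize:
    def test_hand_arithmetic(self):
        s = summarize([1, 2, 3, 4])
        assert s.mean == 2.5 and s.median == 2.5
        assert s.sd == pytest.approx(1.2909944, abs=1e-6)
        assert s.n == 4 and s.min == 1 and s.max == 4

    def test_order_statistics_are_ordered(self, rng):
        s = summarize(rng.lognormal(1, 1, size=37))
        assert s.min <= s.q25 <= s.median <= s.q75 <= s.max

    def test_permutation_invariant(self, rng):
        values = list(rng.normal(size=15))
        shuffled = list(values)
        rng.shuffle(shuffled)
        a, b = summarize(values), summarize(shuffled)
        for name in ("n", "mean", "sd", "median", "q25", "q75", "min", "max"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-12)

    def test_missing_values_dropped_from_n(self):
        assert summarize([1.0, None, 3.0, float("nan")]).n == 2

    def test_empty_raises(self):
        with pytest.raises(DegenerateDataError):
            summarize([])


class TestPairedDifferences:
    def test_direction_is_b_minus_a(self):
        p = paired_differences([1, 2], [2, 1])
        assert p.diffs == (1.0, -1.0)
        assert p.median_diff == 0.0
        assert p.median_abs_diff == 1.0

    def test_identical_inputs(self):
        p = paired_differences([3, 4, 5], [3, 4, 5])
        assert p.median_diff == 0.0 and p.median_abs_diff == 0.0

    def test_pairwise_complete_only(self):
        p = paired_differences([1, None, 3], [2, 5, None])
        assert p.diffs == (1.0,)

    def test_no_complete_pairs_raises(self):
        with pytest.raises(DegenerateDataError):
            paired_differences([None, 1], [2, None])


class TestWilcoxon:
    def test_three_positive_differences_exact(self):
        res = wilcoxon_signed_rank([1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == 0.25
        assert res.method == "exact" and res.n_effective == 3

    def test_symmetric_differences_give_p_one(self):
        # |d| values tie pairwise, so this takes the tie-corrected route,
        # where W+ sits exactly at the null mean
        res = wilcoxon_signed_rank([3, -3, 5, -5, 7, -7])
        assert res.p_value == 1.0
        # tie-free all-balanced case stays on the exact route
        res = wilcoxon_signed_rank([1, -2, 3, -4, 6, -5])
        assert res.method == "exact"

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_exact_p_matches_bruteforce_sign_enumeration(self, rng, n):
        d = rng.normal(size=n)
        res = wilcoxon_signed_rank(d)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_wilcoxon_exact_p(d), abs=1e-12)

    @pytest.mark.parametrize("n", [8, 12, 18])
    def test_exact_p_matches_independent_implementation(self, rng, n):
        d = rng.normal(size=n)
        ours = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, method="exact")
        assert ours.statistic == ref.statistic
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_approximation_matches_independent_implementation(self, rng):
        d = rng.normal(size=40)
        ours = wilcoxon_signed_rank(d, exact_max_n=20)
        ref = stats.wilcoxon(d, correction=True, method="approx")
        assert ours.method == "approximate"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_force_approximation_with_tie_correction(self):
        d = [1.0, -1.0, 2.0, 2.0, -3.0, 4.0, 5.0, -5.0, 6.0]
        ours = wilcoxon_signed_rank(d)
        assert ours.method == "approximate"
        ref = stats.wilcoxon(d, correction=True, method="approx")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_differences_discarded(self):
        with_zeros = wilcoxon_signed_rank([0.0, 0.0, 1, 2, 3])
        assert with_zeros.n_effective == 3
        assert with_zeros.p_value == wilcoxon_signed_rank([1, 2, 3]).p_value

    def test_pratt_zero_method_matches_independent_implementation(self, rng):
        d = np.concatenate([np.zeros(4), rng.normal(size=26)])
        ours = wilcoxon_signed_rank(d, zero_method="pratt")
        ref = stats.wilcoxon(d, zero_method="pratt", correction=True, method="approx")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_agrees_with_approximation_for_moderate_n(self, rng):
        # for n = 15 null draws the two p-value routes should be close
        for _ in range(10):
            d = rng.normal(size=15)
            exact = wilcoxon_signed_rank(d, exact_max_n=20)
            approx = wilcoxon_signed_rank(d, exact_max_n=0)
            assert exact.method == "exact" and approx.method == "approximate"
            assert abs(exact.p_value - approx.p_value) < 0.02

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])


class TestDagostinoPearson:
    def test_null_consistency_on_large_normal_sample(self):
        values = np.random.default_rng(11).normal(size=5000)
        assert dagostino_pearson(values).p_value > 0.01

    def test_detects_lognormal_skew(self):
        values = np.random.default_rng(5).lognormal(0, 1, size=30)
        assert dagostino_pearson(values).p_value < 0.05

    def test_small_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            dagostino_pearson([1, 2, 3, 4, 5, 6, 7])

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateDataError):
            dagostino_pearson([2.0] * 20)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4]).statistic == pytest.approx(1.0)

    def test_ties_equal_bruteforce_rank_pearson(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        rho = spearman(x, y).statistic
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman(x, y)
        transformed = spearman(np.exp(x), y**3)
        assert transformed.statistic == pytest.approx(base.statistic, abs=1e-12)
        assert transformed.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_p_matches_independent_t_approximation(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        ours = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_permutation_close_to_approximation(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=7)
        exact = spearman(x, y, exact=True)
        approx = spearman(x, y)
        assert exact.method == "exact"
        assert exact.statistic == approx.statistic
        assert abs(exact.p_value - approx.p_value) < 0.1

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateDataError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


@pytest.fixture(scope="module")
def report():
    return analyze_cohort(load_reference_cohort())


class TestAnalyzeCohort:
    def test_exclusions_carry_provenance(self, report):
        assert set(report["exclusions"]["pre"]) == {"15"}
        assert set(report["exclusions"]["post"]) == {"7", "8", "9"}
        assert report["pre_resectional"]["n_records"] == 30

    def test_each_statistic_carries_its_n(self, report):
        pre = report["pre_resectional"]
        assert pre["volume_mri_cm3"]["n"] == 30
        assert pre["dice"]["n"] == 30
        assert pre["paired_volume_diff_cm3"]["n"] == 30
        assert report["post_resectional"]["str_subgroup"]["n"] == 10

    def test_excluded_record_contributes_to_no_statistic(self):
        records = load_reference_cohort()
        baseline = analyze_cohort(records)
        # un-exclude the poor-quality case: pre-resectional volumes must move
        for r in records:
            if r.case_id == "15":
                r.exclude_pre = False
        altered = analyze_cohort(records)
        assert altered["pre_resectional"]["volume_mri_cm3"]["n"] == 31
        assert (
            altered["pre_resectional"]["volume_mri_cm3"]["mean"]
            > baseline["pre_resectional"]["volume_mri_cm3"]["mean"]
        )
        # dice/cog columns are missing for that case, so their n stays 30
        assert altered["pre_resectional"]["dice"]["n"] == 30

    def test_volume_distributions_flagged_non_normal(self, report):
        norm = report["pre_resectional"]["normality"]
        assert norm["volume_mri_cm3"]["p_value"] < 0.05
        assert norm["volume_us_cm3"]["p_value"] < 0.05
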