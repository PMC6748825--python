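import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sst

from finchsong.stats import (
    NestRecord,
    anova_omega2,
    classify_match,
    gamma_fit,
    grid_analysis,
    holm_bonferroni,
    nest_medians,
    t_test,
    tradeoff_tests,
    wilcoxon_signed_rank,
)


def make_record(**kw):
    base = dict(bird_id="b", nest_id="n", father_tempo=8.0,
                condition="computer", sd_bits=1.0)
    base.update(kw)
    return NestRecord(**base)


class TestNestMedians:
    def test_median_and_pair_counts(self):
        records = []
        for nest in range(8):
            for sd in (1.0, 2.0, 9.0):
                records.append(make_record(nest_id=f"n{nest}", condition="home",
                                           sd_bits=sd))
            for sd in (3.0, 4.0):
                records.append(make_record(nest_id=f"n{nest}", condition="fostered",
                                           sd_bits=sd))
        pairs = nest_medians(records)
        assert len(pairs) == 8
        assert pairs.loc["n0", "median_home"] == 2.0
        assert pairs.loc["n0", "median_fostered"] == 3.5

    def test_missing_condition_names_nest(self):
        records = [make_record(nest_id="n1", condition="home")]
        with pytest.raises(ValueError, match="n1"):
            nest_medians(records)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            nest_medians([])


def enumerate_wilcoxon_p(diffs):
    """Independent oracle: exact two-sided p by enumerating all 2^n sign
    assignments of the rank statistic under the null."""
    n = len(diffs)
    ranks = sst.rankdata(np.abs(diffs))
    observed = ranks[np.asarray(diffs) > 0].sum()
    total = ranks.sum()
    # two-sided: |W+ - total/2| at least as extreme
    obs_dev = abs(observed - total / 2)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - total / 2) >= obs_dev - 1e-9:
            count += 1
    return count / 2 ** n


class TestWilcoxon:
    def test_all_positive_n8(self):
        pairs = [(i + 2.0, 1.0) for i in range(8)]
        res = wilcoxon_signed_rank(pairs)
        assert res.p_raw == pytest.approx(2 / 256)
        assert "exact" in res.method

    def test_swap_flips_statistic_keeps_p(self):
        pairs = [(3.0, 1.0), (5.0, 2.0), (1.0, 4.0), (7.0, 2.5), (0.5, 2.0),
                 (6.0, 1.5)]
        fwd = wilcoxon_signed_rank(pairs)
        rev = wilcoxon_signed_rank([(b, a) for a, b in pairs])
        assert fwd.p_raw == pytest.approx(rev.p_raw)
        assert fwd.statistic == pytest.approx(-rev.statistic)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])

    @given(
        diffs=st.lists(
            st.integers(-50, 50).filter(lambda d: d != 0),
            min_size=3, max_size=12, unique_by=abs,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_exact_p_matches_enumeration(self, diffs):
        """Exact distribution agrees with brute-force sign enumeration for
        tie-free |differences| up to n = 12."""
        pairs = [(float(d), 0.0) for d in diffs]
        res = wilcoxon_signed_rank(pairs)
        assert res.p_raw == pytest.approx(enumerate_wilcoxon_p(diffs), abs=1e-9)


def brute_force_holm(pvals):
    """Independent oracle: literal step-down definition with monotonicity."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m - rank) * pvals[idx])
        running_max = max(running_max, value)
        adjusted[idx] = running_max
    return list(adjusted)


class TestHolmBonferroni:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03]) == [pytest.approx(0.03)]

    def test_textbook_two_values(self):
        assert holm_bonferroni([0.01, 0.04]) == [
            pytest.approx(0.02), pytest.approx(0.04)
        ]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])

    @given(
        pvals=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1,
                       max_size=10)
    )
    @settings(max_examples=1000, deadline=None)
    def test_matches_brute_force_and_dominates_raw(self, pvals):
        adjusted = holm_bonferroni(pvals)
        expected = brute_force_holm(pvals)
        assert np.allclose(adjusted, expected)
        assert all(a >= p - 1e-12 for a, p in zip(adjusted, pvals))


def manual_omega2(groups):
    """Independent oracle: omega squared from explicit sums of squares."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    k, n = len(groups), all_x.size
    ss_b = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_w = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    ss_t = ((all_x - grand) ** 2).sum()
    ms_w = ss_w / (n - k)
    return max((ss_b - (k - 1) * ms_w) / (ss_t + ms_w), 0.0)


class TestAnovaOmega2:
    def test_identical_means_clamp_to_zero(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [3.0, 2.0, 1.0]]
        assert anova_omega2(groups).effect_size == 0.0

    def test_matches_manual_decomposition(self, rng):
        for _ in range(50):
            groups = [rng.normal(rng.uniform(-2, 2), 1.0, rng.integers(3, 12))
                      for _ in range(rng.integers(2, 5))]
            res = anova_omega2(groups)
            assert res.effect_size == pytest.approx(manual_omega2(groups),
                                                    abs=1e-10)
            f, p = sst.f_oneway(*groups)
            assert res.statistic == pytest.approx(f)
            assert res.p_raw == pytest.approx(p)

    def test_omega2_below_eta2(self, rng):
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 1.0, 2.5)]
        res = anova_omega2(groups)
        all_x = np.concatenate(groups)
        ss_b = sum(len(g) * (g.mean() - all_x.mean()) ** 2 for g in groups)
        eta2 = ss_b / ((all_x - all_x.mean()) ** 2).sum()
        assert res.effect_size <= eta2

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_omega2([[1.0, 2.0], [3.0]])


class TestTTest:
    def test_identical_samples_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = t_test(a, a)
        assert res.p_raw == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_one_tailed_halves_p_in_hypothesized_direction(self, rng):
        a = rng.normal(1.0, 1.0, 12)
        b = rng.normal(0.0, 1.0, 12)
        if a.mean() <= b.mean():
            a, b = b, a
        two = t_test(a, b, tails=2)
        one = t_test(a, b, tails=1, direction="greater")
        assert one.p_raw == pytest.approx(two.p_raw / 2)
        assert one.alpha == 0.025

    def test_power_against_one_sd_shift(self, rng):
        """One-tailed Welch test at alpha 0.025 rejects a 1-SD shift at
        n=10/group more than half the time (Monte-Carlo power check)."""
        hits = 0
        for _ in range(1000):
            a = rng.normal(1.0, 1.0, 10)
            b = rng.normal(0.0, 1.0, 10)
            if t_test(a, b, tails=1, direction="greater").p_raw < 0.025:
                hits += 1
        assert hits / 1000 > 0.5

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0, 1.0], [1.0, 1.0])


class TestGammaFit:
    def test_parameter_recovery(self, rng):
        x = rng.gamma(2.0, 1.0, 10_000)
        fit = gamma_fit(x)
        assert 1.9 < fit.shape < 2.1
        assert fit.scale == pytest.approx(1.0, abs=0.1)

    def test_percentiles_monotone(self, rng):
        fit = gamma_fit(rng.gamma(3.0, 0.5, 500))
        assert fit.p50 < fit.p80

    def test_nonpositive_rejected(self, rng):
        with pytest.raises(ValueError):
            gamma_fit(np.concatenate([rng.gamma(2, 1, 20), [-0.1]]))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            gamma_fit(np.full(20, 2.0))


class TestClassifyMatch:
    @pytest.mark.parametrize(
        "tutor,father,expected",
        [(6.5, 7.18, "matched"), (10.5, 7.18, "tutor_faster"),
         (8.5, 7.89, "matched"), (6.5, 10.31, "tutor_slower")],
    )
    def test_nearest_grid_assignment(self, tutor, father, expected):
        assert classify_match(tutor, father,
                              tutor_grid=(6.5, 8.5, 10.5)) == expected

    def test_tolerance_rule(self):
        assert classify_match(6.5, 7.18, tol=1.0) == "matched"
        assert classify_match(10.5, 7.18, tol=1.0) == "tutor_faster"
        assert classify_match(8.5, 8.5, tol=0.0) == "matched"


class TestGridAnalysis:
    @staticmethod
    def synthetic_records(rng, effect=2.0):
        records = []
        for father in (7.18, 7.89, 10.31):
            for tutor in (6.5, 8.5, 10.5):
                matched = classify_match(tutor, father,
                                         tutor_grid=(6.5, 8.5, 10.5)) == "matched"
                mean = 1.0 if matched else 1.0 + effect
                for i in range(4):
                    records.append(make_record(
                        bird_id=f"{father}-{tutor}-{i}", father_tempo=father,
                        tutor_tempo=tutor,
                        sd_bits=float(max(rng.normal(mean, 0.3), 0.0)),
                    ))
        return records

    def test_matched_category_lowest_and_interaction_dominates(self, rng):
        res = grid_analysis(self.synthetic_records(rng))
        assert res.category_means["matched"] == min(res.category_means.values())
        assert res.category_test.effect_size > res.background_test.effect_size
        assert res.category_test.effect_size > res.tutor_test.effect_size
        assert 0.0 <= res.normalized.to_numpy().min()
        assert res.normalized.to_numpy().max() == pytest.approx(1.0)

    def test_null_effect_gives_small_omega2(self, rng):
        res = grid_analysis(self.synthetic_records(rng, effect=0.0))
        assert res.category_test.effect_size < 0.1

    def test_empty_cell_named(self, rng):
        records = [r for r in self.synthetic_records(rng)
                   if not (r.father_tempo == 7.89 and r.tutor_tempo == 8.5)]
        with pytest.raises(ValueError, match="7.89"):
            grid_analysis(records)

    def test_holm_applied_within_family(self, rng):
        res = grid_analysis(self.synthetic_records(rng))
        for t in (res.category_test, res.background_test, res.tutor_test):
            assert t.p_adjusted is not None
            assert t.p_adjusted >= t.p_raw - 1e-12


class TestTradeoff:
    def test_coupled_records_show_positive_mismatch_correlation(self, rng):
        records = []
        for i in range(30):
            err = rng.uniform(0, 3)
            records.append(make_record(
                bird_id=str(i), tutor_tempo=8.5, tutee_tempo=8.5 + err,
                sd_bits=float(max(0.5 + 2 * err + rng.normal(0, 0.5), 0.0)),
            ))
        res = tradeoff_tests(records)
        mismatch = [t for t in res if "tempo error" in t.method][0]
        assert mismatch.statistic > 0.5

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            tradeoff_tests([make_record(tutor_tempo=8.5, tutee_tempo=8.0)])

    def test_degenerate_sd_rejected(self):
        records = [make_record(bird_id=str(i), tutor_tempo=8.5,
                               tutee_tempo=8.0 + i, sd_bits=1.0)
                   for i in range(5)]
        with pytest.raises(ValueError, match="degenerate"):
            tradeoff_tests(records)
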