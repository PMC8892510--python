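"""Survival estimation, log-rank contrasts, and cross genetics.

The log-rank implementation is cross-checked against a hand-coded
statistic plus a label-permutation oracle; the chi-square homogeneity
test against a closed-form Pearson computation.
"""

import numpy as np
import pytest

from flypheno import cohortstats, synthgen
from flypheno.types import CrossSpec, GenotypeCounts, ParameterError, SurvivalCohort


def cohort(days, events=None, **kw):
    days = np.asarray(days, dtype=float)
    if events is None:
        events = np.ones(days.size, dtype=int)
    return SurvivalCohort.from_arrays(days, events, **kw)


def logrank_statistic_oracle(days, events, group):
    """Hand-coded two-group log-rank statistic (hypergeometric moments)."""
    days = np.asarray(days, float)
    events = np.asarray(events, int)
    group = np.asarray(group, bool)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(days[events == 1]):
        at_risk = days >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((days == t) & (events == 1)).sum()
        d1 = ((days == t) & (events == 1) & group).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


class TestKaplanMeier:
    def test_uncensored_deaths_reproduce_empirical_survival(self):
        curve = cohortstats.km_estimate(cohort(np.arange(1, 8)))
        assert cohortstats.survival_at(curve, 4) == pytest.approx(3 / 7)
        assert curve.median == pytest.approx(4)

    def test_all_censored_curve_stays_at_one(self):
        curve = cohortstats.km_estimate(cohort([5, 6, 7], events=[0, 0, 0]))
        assert np.all(curve.survival == 1.0)
        assert curve.median is None

    def test_km_equals_empirical_sf_without_censoring(self):
        rng = np.random.default_rng(0)
        days = rng.integers(1, 40, size=60).astype(float)
        curve = cohortstats.km_estimate(cohort(days))
        for t in (0.0, 5.0, 17.5, 39.0, 60.0):
            assert cohortstats.survival_at(curve, t) == pytest.approx(
                np.mean(days > t)
            )

    def test_generator_median_recovered(self):
        co = synthgen.gen_survival_cohort(2000, 74.0, shape=5, seed=1)
        assert cohortstats.km_estimate(co).median == pytest.approx(74.0, abs=2.0)

    def test_exponential_cohort_survival_half_at_median(self):
        co = synthgen.gen_survival_cohort(4000, 20.0, shape=1, seed=2)
        curve = cohortstats.km_estimate(co)
        assert cohortstats.survival_at(curve, 20.0) == pytest.approx(0.5, abs=0.03)

    def test_survival_at_boundaries(self):
        curve = cohortstats.km_estimate(cohort([1, 2, 3]))
        assert cohortstats.survival_at(curve, 0) == 1.0
        assert cohortstats.survival_at(curve, 10) == 0.0


class TestLogrank:
    def test_identical_cohorts_give_null_result(self):
        a = cohort(np.arange(1, 21))
        res = cohortstats.logrank_test(a, a)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_statistic_matches_hand_coded_oracle(self):
        a = synthgen.gen_survival_cohort(20, 60, shape=4, seed=3)
        b = synthgen.gen_survival_cohort(20, 75, shape=4, seed=4)
        res = cohortstats.logrank_test(a, b)
        days = np.concatenate([a.days, b.days])
        events = np.concatenate([a.events, b.events])
        group = np.arange(40) < 20
        assert res.statistic == pytest.approx(
            logrank_statistic_oracle(days, events, group), rel=1e-6
        )

    def test_p_value_agrees_with_permutation_oracle(self):
        # rank of the observed statistic among 1e4 label shuffles; the
        # asymptotic chi-square p should agree up to small-sample error
        a = synthgen.gen_survival_cohort(20, 60, shape=4, seed=3)
        b = synthgen.gen_survival_cohort(20, 75, shape=4, seed=4)
        days = np.concatenate([a.days, b.days])
        events = np.concatenate([a.events, b.events])
        observed = logrank_statistic_oracle(days, events, np.arange(40) < 20)
        rng = np.random.default_rng(5)
        perm = np.empty(10_000)
        for i in range(perm.size):
            g = np.zeros(40, bool)
            g[rng.choice(40, 20, replace=False)] = True
            perm[i] = logrank_statistic_oracle(days, events, g)
        p_perm = np.mean(perm >= observed)
        p_chi2 = cohortstats.logrank_test(a, b).p_value
        assert p_chi2 == pytest.approx(p_perm, abs=0.03)

    def test_widely_separated_medians_are_overwhelming(self):
        a = synthgen.gen_survival_cohort(100, 20, shape=5, seed=6)
        b = synthgen.gen_survival_cohort(100, 80, shape=5, seed=7)
        assert cohortstats.logrank_test(a, b).p_value < 1e-6

    def test_statistic_invariant_to_time_rescaling(self):
        a = synthgen.gen_survival_cohort(30, 50, shape=4, seed=8)
        b = synthgen.gen_survival_cohort(30, 65, shape=4, seed=9)
        res1 = cohortstats.logrank_test(a, b)
        a2 = cohort(a.days * 24.0, a.events)
        b2 = cohort(b.days * 24.0, b.events)
        res2 = cohortstats.logrank_test(a2, b2)
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-9)


class TestCrossGenetics:
    SELF_CROSS = CrossSpec(("hWT", "TM6B"), ("hWT", "TM6B"))

    def test_balancer_self_cross_enumeration(self):
        # 4 gamete combinations, drop TM6B/TM6B: 1/3 homozygous, 2/3 balanced
        freqs = cohortstats.expected_cross_frequencies(self.SELF_CROSS)
        assert freqs["hWT/hWT"] == pytest.approx(1 / 3)
        assert freqs["TM6B/hWT"] == pytest.approx(2 / 3)

    def test_frequencies_form_a_distribution(self):
        cross = CrossSpec(
            ("hD33V", "TM6B"), ("hR95H", "TM6B"), {"hD33V/hR95H": 0.4}
        )
        freqs = cohortstats.expected_cross_frequencies(cross)
        assert sum(freqs.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in freqs.values())

    def test_inviable_homozygote_shifts_mass_to_balanced_class(self):
        cross = CrossSpec(
            ("hR95H", "TM6B"), ("hR95H", "TM6B"), {"hR95H/hR95H": 0.0}
        )
        freqs = cohortstats.expected_cross_frequencies(cross)
        assert freqs == {"TM6B/hR95H": 1.0}

    def test_fully_inviable_cross_rejected(self):
        cross = CrossSpec(
            ("hR95H", "TM6B"), ("hR95H", "TM6B"),
            {"hR95H/hR95H": 0.0, "TM6B/hR95H": 0.0},
        )
        with pytest.raises(ParameterError):
            cohortstats.expected_cross_frequencies(cross)


class TestHomozygosityRatio:
    def test_simple_ratio(self):
        counts = GenotypeCounts({"hWT/hWT": 50, "TM6B/hWT": 100})
        ratio, _ = cohortstats.homozygosity_ratio(counts)
        assert ratio == pytest.approx(1 / 3)

    def test_absent_homozygotes_give_zero_ratio(self):
        counts = GenotypeCounts({"hR95H/hR95H": 0, "TM6B/hR95H": 200})
        ratio, (lo, hi) = cohortstats.homozygosity_ratio(counts)
        assert ratio == 0.0
        assert lo == pytest.approx(0.0, abs=1e-12)

    def test_generator_ratio_within_wilson_ci_of_one_third(self):
        counts = synthgen.gen_cross_offspring(
            CrossSpec(("hWT", "TM6B"), ("hWT", "TM6B")), 3000, seed=20
        )
        _, (lo, hi) = cohortstats.homozygosity_ratio(counts)
        assert lo <= 1 / 3 <= hi

    def test_zero_total_rejected(self):
        with pytest.raises(ParameterError):
            cohortstats.homozygosity_ratio(GenotypeCounts({"hWT/hWT": 0}))


class TestChi2Homogeneity:
    def test_identical_proportions_give_zero_statistic(self):
        a = GenotypeCounts({"hWT/hWT": 10, "TM6B/hWT": 20})
        b = GenotypeCounts({"hWT/hWT": 30, "TM6B/hWT": 60})
        res = cohortstats.chi2_homogeneity(a, b)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_pearson_oracle(self):
        a = GenotypeCounts({"hR95H/hR95H": 0, "TM6B/hR95H": 100})
        b = GenotypeCounts({"hWT/hWT": 33, "TM6B/hWT": 67})
        res = cohortstats.chi2_homogeneity(a, b)
        # independent closed-form Pearson sum over the 2x2 table
        obs = np.array([[0, 100], [33, 67]], float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        oracle = ((obs - exp) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(oracle, rel=1e-9)
        assert res.df == 1

    def test_empty_margin_rejected(self):
        a = GenotypeCounts({"hWT/hWT": 0, "TM6B/hWT": 0})
        b = GenotypeCounts({"hWT/hWT": 10, "TM6B/hWT": 10})
        with pytest.raises(ParameterError):
            cohortstats.chi2_homogeneity(a, b)


class TestDominanceContrast:
    def test_identical_cohorts_have_no_difference(self):
        a = cohort(np.arange(1, 31), genotype="hR95H/hWT")
        res, diff, flag = cohortstats.dominance_contrast(a, a)
        assert diff == 0
        assert flag == "no median difference"

    def test_swapping_inputs_negates_median_difference(self):
        a = synthgen.gen_survival_cohort(100, 19, shape=3, seed=11)
        b = synthgen.gen_survival_cohort(100, 27, shape=3, seed=12)
        _, d_ab, _ = cohortstats.dominance_contrast(a, b)
        _, d_ba, _ = cohortstats.dominance_contrast(b, a)
        assert d_ab == pytest.approx(-d_ba)

    def test_shorter_lived_mutant_het_flags_dominant_negative(self):
        # true medians 19 vs 27 days, n = 135 per arm
        a = synthgen.gen_survival_cohort(135, 19, shape=3, seed=13)
        b = synthgen.gen_survival_cohort(135, 27, shape=3, seed=14)
        res, diff, flag = cohortstats.dominance_contrast(a, b)
        assert res.p_value < 0.001
        assert diff == pytest.approx(-8.0, abs=3.0)
        assert flag == "consistent with dominant-negative"
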