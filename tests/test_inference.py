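import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import allelefish as af
from allelefish.data import LocusClass, Sex, SignalCountSummary
from allelefish.inference import SmallExpectedCountWarning


class TestEfficiency:
    def test_point_estimate_from_single_copy_counts(self):
        s = SignalCountSummary("z1", Sex.HETEROGAMETIC, n2=0, n1=95, n0=5)
        est = af.estimate_efficiency(s)
        assert est.p_hat == pytest.approx(0.95)
        assert est.q_hat == pytest.approx(0.05)
        assert est.n_het == 100

    def test_perfect_detection(self):
        s = SignalCountSummary("z1", Sex.HETEROGAMETIC, n2=0, n1=100, n0=0)
        assert af.estimate_efficiency(s).p_hat == 1.0

    def test_two_signal_nuclei_warn_and_are_excluded(self):
        s = SignalCountSummary("z1", Sex.HETEROGAMETIC, n2=3, n1=90, n0=10)
        with pytest.warns(UserWarning, match="two signals"):
            est = af.estimate_efficiency(s)
        assert est.n_het == 100

    def test_wrong_sex_and_empty_rejected(self):
        hom = SignalCountSummary("z1", Sex.HOMOGAMETIC, n2=0, n1=95, n0=5)
        with pytest.raises(ValueError, match="heterogametic"):
            af.estimate_efficiency(hom)
        empty = SignalCountSummary("z1", Sex.HETEROGAMETIC, n2=0, n1=0, n0=0)
        with pytest.raises(ValueError, match="no usable"):
            af.estimate_efficiency(empty)

    def test_simulated_estimate_within_exact_binomial_band(self):
        """At true p = 0.97 and n = 5000 heterogametic nuclei the estimate
        lands inside the exact binomial 99% interval around the truth."""
        config = af.SimConfig(
            loci=(af.SimLocus("z1", LocusClass.SEX_SPECIFIC, 0.3, 0.97),),
            n_homogametic=0,
            n_heterogametic=5000,
            tetraploid_fraction=0.0,
            control_efficiency=1.0,
            seed=17,
        )
        summaries = af.simulate_summaries(config)
        est = af.estimate_efficiency(summaries[("z1", Sex.HETEROGAMETIC)])
        n = est.n_het
        lo = stats.binom.ppf(0.005, n, 0.97) / n
        hi = stats.binom.ppf(0.995, n, 0.97) / n
        assert lo <= est.p_hat <= hi


class TestNullDistribution:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.95, (0.9025, 0.095, 0.0025)),
            (1.0, (1.0, 0.0, 0.0)),
            (0.5, (0.25, 0.5, 0.25)),
        ],
    )
    def test_known_values(self, p, expected):
        null = af.null_distribution(p)
        assert (null.f2, null.f1, null.f0) == pytest.approx(expected)

    @settings(derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_fractions_sum_to_one(self, p):
        null = af.null_distribution(p)
        assert null.f2 + null.f1 + null.f0 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_domain_error(self, p):
        with pytest.raises(ValueError):
            af.null_distribution(p)


class TestInactivationTest:
    def test_strong_excess_is_significant(self):
        # hand-computed Pearson table: O=(60,35,5), E=(90.25,9.5,0.25)
        # -> 10.1392 + 68.4474 + 90.25 = 168.8366
        obs = SignalCountSummary("z1", Sex.HOMOGAMETIC, n2=60, n1=35, n0=5)
        eff = af.EfficiencyEstimate("z1", 0.95, 100)
        with pytest.warns(SmallExpectedCountWarning):
            chi2, df, p = af.test_inactivation(obs, eff)
        assert chi2 == pytest.approx(168.8366, abs=1e-3)
        assert df == 2
        assert chi2 > stats.chi2.ppf(0.99, 2)
        assert p < 0.01

    def test_perfect_fit_gives_chi2_near_zero(self):
        # n = 400 at p = 0.95 makes all three expected counts integers
        obs = SignalCountSummary("z1", Sex.HOMOGAMETIC, n2=361, n1=38, n0=1)
        eff = af.EfficiencyEstimate("z1", 0.95, 100)
        chi2, _, p = af.test_inactivation(obs, eff)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_expected_with_nonzero_observed_flags_infinite(self):
        obs = SignalCountSummary("z1", Sex.HOMOGAMETIC, n2=90, n1=8, n0=2)
        eff = af.EfficiencyEstimate("z1", 1.0, 100)
        chi2, _, p = af.test_inactivation(obs, eff)
        assert math.isinf(chi2) and p == 0.0


class TestBonferroni:
    def test_definition_and_cap(self):
        assert af.bonferroni([0.001, 0.5], 10) == [0.01, 1.0]

    def test_identity_family_of_one(self):
        assert af.bonferroni([0.2], 1) == [0.2]

    @settings(derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8),
        st.integers(min_value=8, max_value=50),
    )
    def test_monotone_and_order_preserving(self, ps, family):
        out = af.bonferroni(ps, family)
        assert len(out) == len(ps)
        assert all(o >= p for o, p in zip(out, ps))
        assert all(0.0 <= o <= 1.0 for o in out)

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            af.bonferroni([0.1], 0)
        with pytest.raises(ValueError):
            af.bonferroni([0.1, 0.2], 1)


class TestPoissonExactCI:
    def test_printed_reference_values(self):
        lo, hi = af.poisson_exact_ci(40)
        assert lo == pytest.approx(28.58, abs=0.005)
        assert hi == pytest.approx(54.47, abs=0.005)
        assert af.poisson_exact_ci(69)[1] == pytest.approx(87.32, abs=0.005)

    def test_zero_count(self):
        lo, hi = af.poisson_exact_ci(0)
        assert lo == 0.0
        # ½·χ²-quantile(0.975, 2 df) = −ln(0.025)
        assert hi == pytest.approx(-math.log(0.025), abs=1e-9)

    @settings(derandomize=True)
    @given(st.integers(min_value=1, max_value=500))
    def test_interval_brackets_count_and_grows(self, k):
        lo, hi = af.poisson_exact_ci(k)
        assert lo <= k <= hi
        lo2, hi2 = af.poisson_exact_ci(k + 1)
        assert lo2 > lo and hi2 > hi

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            af.poisson_exact_ci(5, level=1.0)

    def test_coverage_over_reference_rates(self):
        """Exact intervals cover the true rate in ≥95% of draws."""
        rng = np.random.default_rng(9)
        for lam in (1, 5, 20, 40, 69):
            ks = rng.poisson(lam, 1500)
            covered = np.mean(
                [lo <= lam <= hi for lo, hi in (af.poisson_exact_ci(int(k)) for k in ks)]
            )
            assert covered >= 0.95


class TestErrorEstimate:
    def test_chicken_control_tally(self):
        n2 = 1756 - 12 - 16
        s = SignalCountSummary("a1", Sex.HOMOGAMETIC, n2=n2, n1=16, n0=12)
        err = af.estimate_error([s], species="chicken")
        assert err.missed == 40
        assert err.expected_signals == 3512
        assert err.raw_rate * 100 == pytest.approx(1.14, abs=0.005)
        assert err.max_error_rate * 100 == pytest.approx(1.55, abs=0.005)

    def test_platypus_control_tally(self):
        # 1884 nuclei / 69 missed split as 10 zero-signal + 49 one-signal
        s = SignalCountSummary("a1", Sex.HOMOGAMETIC, n2=1884 - 59, n1=49, n0=10)
        err = af.estimate_error([s], species="platypus")
        assert err.missed == 69
        assert err.expected_signals == 3768
        assert err.ci_high == pytest.approx(87.32, abs=0.005)
        assert err.max_error_rate * 100 == pytest.approx(2.32, abs=0.005)

    def test_split_across_experiments_is_equivalent(self):
        parts = [
            SignalCountSummary("a1", Sex.HOMOGAMETIC, n2=800, n1=10, n0=6),
            SignalCountSummary("a2", Sex.HETEROGAMETIC, n2=928, n1=6, n0=6),
        ]
        err = af.estimate_error(parts)
        assert err.missed == 40 and err.n_nuclei == 1756

    def test_no_misses(self):
        s = SignalCountSummary("a1", Sex.HOMOGAMETIC, n2=500, n1=0, n0=0)
        err = af.estimate_error([s])
        assert err.missed == 0 and err.raw_rate == 0.0 and err.ci_low == 0.0

    def test_rejects_empty_and_non_autosomal(self):
        with pytest.raises(ValueError):
            af.estimate_error([])
        s = SignalCountSummary("z1", Sex.HOMOGAMETIC, n2=10, n1=0, n0=0)
        with pytest.raises(ValueError, match="non-autosomal"):
            af.estimate_error([s], locus_classes={"z1": "sex_specific"})


class TestAdjustAndRetest:
    def test_percentage_point_shift(self):
        # observed 1-active fraction 0.30 vs renormalized expected 0.0952
        # shifted by 1.55 points -> 0.2845
        obs = SignalCountSummary("z1", Sex.HOMOGAMETIC, n2=140, n1=60, n0=0)
        eff = af.EfficiencyEstimate("z1", 0.95, 100)
        (adj2, adj1), chi2, df, p = af.adjust_and_retest(obs, eff, 0.0155)
        assert adj1 / 200 == pytest.approx(0.2845, abs=1e-9)
        assert df == 1 and p < 0.01

    def test_zero_rate_matches_unadjusted_two_category_statistic(self, strong_summary):
        eff = af.EfficiencyEstimate("z1", 0.95, 100)
        (adj2, adj1), chi2, _, _ = af.adjust_and_retest(strong_summary, eff, 0.0)
        assert (adj2, adj1) == pytest.approx((strong_summary.n2, strong_summary.n1))
        n = strong_summary.n2 + strong_summary.n1
        e2 = 0.9025 / 0.9975
        expected_chi2 = (
            (strong_summary.n2 - n * e2) ** 2 / (n * e2)
            + (strong_summary.n1 - n * (1 - e2)) ** 2 / (n * (1 - e2))
        )
        assert chi2 == pytest.approx(expected_chi2)

    def test_shift_never_overshoots_expected(self):
        eff = af.EfficiencyEstimate("z1", 0.95, 100)
        e2 = 0.9025 / 0.9975
        # observed within 1.55 points of expected: adjustment clamps exactly
        n2 = round(199 * e2)
        obs = SignalCountSummary("z1", Sex.HOMOGAMETIC, n2=n2, n1=199 - n2, n0=1)
        (adj2, _), chi2, _, p = af.adjust_and_retest(obs, eff, 0.0155)
        assert adj2 / 199 == pytest.approx(e2, abs=1e-9)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_proportional_mode(self, strong_summary):
        eff = af.EfficiencyEstimate("z1", 0.95, 100)
        n = strong_summary.n2 + strong_summary.n1
        e2 = 0.9025 / 0.9975
        o2 = strong_summary.n2 / n
        (adj2, _), *_ = af.adjust_and_retest(strong_summary, eff, 0.1, mode="proportional")
        assert adj2 / n == pytest.approx(o2 + 0.1 * (e2 - o2))

    def test_degenerate_input_rejected(self):
        obs = SignalCountSummary("z1", Sex.HOMOGAMETIC, n2=0, n1=0, n0=10)
        eff = af.EfficiencyEstimate("z1", 0.95, 100)
        with pytest.raises(ValueError):
            af.adjust_and_retest(obs, eff, 0.01)
        with pytest.raises(ValueError):
            af.adjust_and_retest(obs, eff, 0.6)


class TestRobustnessSweep:
    def test_strong_signal_survives_conservative_error(self, strong_summary):
        """A 40% 1-active locus stays significant even shifted 5 points."""
        eff = af.EfficiencyEstimate("z1", 0.97, 200)
        rows = af.robustness_sweep(
            strong_summary, eff, [0.0, 0.0155, 0.05], family_size=11
        )
        assert [r["error_rate"] for r in rows] == [0.0, 0.0155, 0.05]
        assert all(r["significant"] for r in rows)

    def test_single_zero_rate_equals_unadjusted(self, strong_summary):
        eff = af.EfficiencyEstimate("z1", 0.97, 200)
        row = af.robustness_sweep(strong_summary, eff, [0.0])[0]
        _, chi2, _, p = af.adjust_and_retest(strong_summary, eff, 0.0)
        assert row["chi2"] == chi2 and row["p"] == p

    def test_p_nondecreasing_in_error_rate_above_expectation(self, strong_summary):
        eff = af.EfficiencyEstimate("z1", 0.97, 200)
        grid = [0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.1]
        rows = af.robustness_sweep(strong_summary, eff, grid)
        ps = [r["p"] for r in rows]
        assert all(b >= a for a, b in zip(ps, ps[1:]))


class TestSilencingEstimate:
    def test_inverts_the_generative_one_signal_fraction(self):
        # s=0.4, p=0.95: f1 = 2pq + s*p*(2p-1) = 0.095 + 0.342 = 0.437
        n = 10000
        f1 = 0.437
        f2 = 0.95 * 0.6 * 0.95  # p * (1-s) * p
        obs = SignalCountSummary(
            "z1", Sex.HOMOGAMETIC,
            n2=round(n * f2), n1=round(n * f1), n0=n - round(n * f2) - round(n * f1),
        )
        eff = af.EfficiencyEstimate("z1", 0.95, 1000)
        assert af.estimate_silencing(obs, eff) == pytest.approx(0.4, abs=1e-3)

    def test_clamped_to_unit_interval_and_identifiability_guard(self):
        obs = SignalCountSummary("z1", Sex.HOMOGAMETIC, n2=100, n1=0, n0=0)
        eff = af.EfficiencyEstimate("z1", 0.95, 100)
        assert af.estimate_silencing(obs, eff) == 0.0
        with pytest.raises(ValueError, match="identifiable"):
            af.estimate_silencing(obs, af.EfficiencyEstimate("z1", 0.5, 100))
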