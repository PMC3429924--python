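"""Mosaic statistics: size classes, f, geometric and Poisson models."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wingmosaic import (
    SimulationConfig,
    chisq_gof,
    compare_frequencies,
    estimate_loss_probability,
    expected_mosaic_statistics,
    halve_by_half_expected,
    poisson_expected,
    recover_loss_rate,
    size_class,
    summarize_group,
)


class TestSizeClass:
    @pytest.mark.parametrize(
        "size,cls",
        [(1, 1), (2, 2), (3, 3), (4, 3), (5, 4), (8, 4), (9, 5), (16, 5),
         (32, 6), (33, 7), (64, 7), (65, 8), (128, 8), (129, 9), (256, 9)],
    )
    def test_class_boundaries(self, size, cls):
        assert size_class(size) == cls

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            size_class(0)

    @given(st.integers(1, 10_000))
    def test_non_decreasing_and_power_of_two_exact(self, s):
        assert size_class(s + 1) >= size_class(s)
        if s > 1 and (s & (s - 1)) == 0:  # s is a power of two
            assert size_class(s) == int(math.log2(s)) + 1
            assert size_class(s + 1) == size_class(s) + 1


class TestSummarizeGroup:
    def test_control_row_frequency(self):
        s = summarize_group(
            class_counts=(96, 39, 22, 5, 2), N=108, C=30000,
            m_override=1.7, group="control",
        )
        assert s.n == 164
        assert s.f_per_1e4 == 1.7
        assert s.clones_per_wing == pytest.approx(164 / 108)

    def test_xray_mean_class_rounds_to_published_m(self):
        s = summarize_group(
            class_counts=(37, 31, 19, 15, 9, 4, 2, 2), N=12, C=30000
        )
        assert s.n == 119
        assert s.mean_class == pytest.approx(315 / 119)
        assert s.m == 2.6
        assert s.f_per_1e4 == 17.2

    def test_single_unit_clone(self):
        s = summarize_group([1], N=1, C=30000)
        assert s.f == pytest.approx(2 / 30000)

    def test_empty_group_flagged_not_raised(self):
        s = summarize_group([], N=5, C=30000)
        assert s.n == 0
        assert s.f == 0.0
        assert math.isnan(s.m)
        assert math.isnan(s.target_cells)

    def test_f_linear_in_n_and_m_inverse_in_N_and_C(self):
        base = summarize_group([1] * 10, N=5, C=30000)
        assert summarize_group([1] * 20, N=5, C=30000).f == pytest.approx(2 * base.f)
        assert summarize_group([1] * 10, N=10, C=30000).f == pytest.approx(base.f / 2)
        assert summarize_group([1] * 10, N=5, C=60000).f == pytest.approx(base.f / 2)
        doubled_m = summarize_group([1] * 10, N=5, C=30000, m_override=2.0)
        assert doubled_m.f == pytest.approx(2 * base.f)

    def test_class_counts_consistency(self):
        s = summarize_group([1, 1, 2, 3, 4, 7, 20], N=3, C=1000)
        assert sum(s.class_counts) == s.n == 7
        assert s.class_counts[:6] == (2, 1, 2, 1, 0, 1)


class TestHalveByHalf:
    def test_control_expectation(self):
        exp = halve_by_half_expected(164, 5)
        assert exp.expected_rounded == (85, 42, 21, 11, 5)
        assert exp.expected == pytest.approx(
            (84.645, 42.323, 21.161, 10.581, 5.290), abs=5e-4
        )

    def test_zero_clones(self):
        assert halve_by_half_expected(0, 4).expected == (0, 0, 0, 0)

    def test_single_class_takes_all(self):
        assert halve_by_half_expected(7, 1).expected == (7,)

    @given(st.integers(0, 5000), st.integers(1, 12))
    def test_expectation_sums_exactly_to_n(self, n, K):
        assert sum(halve_by_half_expected(n, K).expected) == pytest.approx(
            n, abs=1e-9
        )


class TestPoisson:
    def test_control_expected_wing_counts(self):
        fit = poisson_expected(164, 108, 6)
        assert fit.nu == pytest.approx(164 / 108)
        assert fit.expected == pytest.approx(
            (23.7, 35.9, 27.3, 13.8, 5.2, 1.6, 0.4), abs=0.05
        )

    def test_zero_rate(self):
        fit = poisson_expected(0, 10, 3)
        assert fit.expected == pytest.approx((10, 0, 0, 0))

    def test_truncation_mass_accounts_for_tail(self):
        fit = poisson_expected(164, 108, 6)
        assert sum(fit.expected) + fit.truncated_mass == pytest.approx(108)

    def test_gof_with_observed(self):
        observed = (30, 28, 29, 10, 7, 4, 0)
        fit = poisson_expected(164, 108, 6, observed=observed)
        assert fit.pvalue > 0.05
        assert sum(fit.pooled_observed) == 108
        # pooling merged the sparse tail but left reported expecteds intact
        assert len(fit.pooled_expected) < len(fit.expected)
        assert len(fit.expected) == 7


class TestChisqGof:
    def test_perfect_fit(self):
        stat, df, p = chisq_gof([10, 5, 2], [10, 5, 2], pool_below=0.0)
        assert stat == 0.0
        assert p == 1.0

    def test_statistic_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            k = rng.integers(2, 8)
            exp = rng.uniform(2.0, 30.0, size=k)  # no pooling triggers
            obs = rng.poisson(exp)
            stat, df, _ = chisq_gof(obs, exp, pool_below=1.0)
            oracle = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
            assert stat == pytest.approx(oracle)
            assert df == k - 1

    def test_all_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            chisq_gof([1, 2], [0, 0])

    def test_estimated_rate_df_correction(self):
        obs = (30, 28, 29, 10, 7, 4, 0)
        fit = poisson_expected(164, 108, 6, observed=obs, estimate_rate_df=True)
        plain = poisson_expected(164, 108, 6, observed=obs)
        assert fit.df == plain.df - 1
        assert fit.pvalue > 0.05  # the conclusion is insensitive to the flag


class TestCompareFrequencies:
    def test_control_pooling_groups_are_homogeneous(self):
        stat, df, p = compare_frequencies([(86, 58), (22, 16), (56, 34)])
        assert df == 2
        assert p > 0.05
        # expected counts under the common rate
        total_n, total_N = 164, 108
        assert total_n * 58 / total_N == pytest.approx(88.07, abs=0.01)
        assert total_n * 16 / total_N == pytest.approx(24.30, abs=0.01)
        assert total_n * 34 / total_N == pytest.approx(51.63, abs=0.01)

    def test_identical_groups_give_zero(self):
        stat, _, p = compare_frequencies([(40, 20), (40, 20)])
        assert stat == 0.0
        assert p == 1.0

    def test_grossly_unequal_groups_rejected(self):
        stat, df, p = compare_frequencies([(100, 10), (0, 10)])
        # oracle: expectation (50, 50) -> chi2 = 50 + 50 = 100
        assert stat == pytest.approx(100.0)
        assert p < 0.01

    def test_degenerate_all_zero(self):
        with pytest.warns(UserWarning):
            stat, _, p = compare_frequencies([(0, 5), (0, 5)])
        assert p == 1.0


class TestLossRateRecovery:
    def test_zero_clones_estimates_zero(self):
        est = recover_loss_rate([[], [], []], C=30000, n_bootstrap=10, seed=0)
        assert est.f_hat == 0.0

    def test_doubling_C_halves_estimate(self):
        wings = [[1, 2], [1], []]
        a = recover_loss_rate(wings, C=30000, n_bootstrap=0)
        b = recover_loss_rate(wings, C=60000, n_bootstrap=0)
        assert b.f_hat == pytest.approx(a.f_hat / 2)

    def test_single_wing_has_no_interval(self):
        est = recover_loss_rate([[1, 1]], C=30000, n_bootstrap=50, seed=0)
        assert est.f_interval is None

    def test_estimator_inversion_round_trips(self):
        config = SimulationConfig(seed=0)
        for p in (1e-4, 1e-3, 1e-2):
            f = expected_mosaic_statistics(config, p).expected_f
            assert estimate_loss_probability(f, config) == pytest.approx(
                p, rel=1e-6
            )

    def test_expected_f_exceeds_p_under_multiround_exposure(self):
        """The published estimator counts losses from every division round
        but normalises by one effective target count, so its expectation
        sits above the per-division rate."""
        config = SimulationConfig(seed=0)
        for p in (1e-4, 1e-3):
            exp = expected_mosaic_statistics(config, p)
            assert exp.expected_f > 1.5 * p
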