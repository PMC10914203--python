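"""Paired resampled inference: iterated signed-rank tests, relative risks,
baseline comparisons and correlations."""
import numpy as np
import pytest
from scipy import stats as sps

from ppgarousal.stats import (
    IteratedTestResult,
    baseline_compare,
    iterated_wilcoxon,
    magnitude_delay_correlation,
    relative_risk,
    signed_rank_p,
)


class TestIteratedWilcoxon:
    def test_identical_groups_degenerate_p_one(self):
        g = {"s1": [2.0], "s2": [3.0]}
        res = iterated_wilcoxon(g, g, n_iter=20, rng=np.random.default_rng(0))
        assert res.degenerate
        assert res.median_p == 1.0

    def test_unique_pairing_collapses_to_standard_test(self):
        # one measurement per subject per group: pairing is forced, so the
        # iterated median equals the direct signed-rank p-value
        rng = np.random.default_rng(1)
        a_vals = rng.normal(0.5, 1.0, size=12)
        b_vals = rng.normal(0.0, 1.0, size=12)
        ga = {f"s{i}": [float(a_vals[i])] for i in range(12)}
        gb = {f"s{i}": [float(b_vals[i])] for i in range(12)}
        res = iterated_wilcoxon(ga, gb, n_iter=50, rng=np.random.default_rng(2))
        direct = sps.wilcoxon(a_vals - b_vals, method="exact").pvalue
        assert res.median_p == pytest.approx(direct)
        assert np.all(res.p_values == res.p_values[0])

    def test_planted_shift_detected_one_sided(self):
        # 40 subjects, ~1-pooled-sd shift: median one-sided p below 0.01
        rng = np.random.default_rng(3)
        ga, gb = {}, {}
        for i in range(40):
            n = rng.integers(1, 4)
            ga[f"s{i}"] = list(rng.normal(1.0, 1.0, n))
            gb[f"s{i}"] = list(rng.normal(0.0, 1.0, rng.integers(1, 4)))
        res = iterated_wilcoxon(ga, gb, n_iter=200, alternative="greater",
                                rng=np.random.default_rng(4))
        assert res.median_p < 0.01

    def test_no_shared_subjects_raises(self):
        with pytest.raises(ValueError, match="no paired support"):
            iterated_wilcoxon({"a": [1.0]}, {"b": [1.0]}, n_iter=5)

    def test_fixed_seed_reproducible(self):
        rng_a = np.random.default_rng(7)
        rng_b = np.random.default_rng(7)
        ga = {f"s{i}": [float(i), float(i) / 2] for i in range(8)}
        gb = {f"s{i}": [float(i) - 0.3] for i in range(8)}
        r1 = iterated_wilcoxon(ga, gb, n_iter=50, rng=rng_a)
        r2 = iterated_wilcoxon(ga, gb, n_iter=50, rng=rng_b)
        assert r1.median_p == r2.median_p

    def test_monotone_power_in_effect_size(self):
        # rejection frequency must not decrease as the planted shift grows
        def rejection_rate(shift, n_rep=50):
            hits = 0
            for rep in range(n_rep):
                rng = np.random.default_rng(100 * rep + int(shift * 10))
                ga = {f"s{i}": list(rng.normal(shift, 1.0, 2)) for i in range(15)}
                gb = {f"s{i}": list(rng.normal(0.0, 1.0, 2)) for i in range(15)}
                res = iterated_wilcoxon(ga, gb, n_iter=30, alternative="greater",
                                        rng=rng)
                hits += res.median_p < 0.01
            return hits / n_rep

        rates = [rejection_rate(s) for s in (0.0, 0.8, 1.6)]
        assert rates[0] <= rates[1] <= rates[2]


class TestRelativeRisk:
    def test_equal_rates_give_unity(self):
        res = relative_risk(15, 60, 10, 40)
        assert res.rr == pytest.approx(1.0)
        assert res.ci99[0] < 1.0 < res.ci99[1]
        assert not res.significant

    def test_hand_computed_interval(self):
        # (20/100) / (10/100) = 2; CI from the log-normal formula, z = 2.5758
        res = relative_risk(20, 100, 10, 100)
        assert res.rr == pytest.approx(2.0)
        z = 2.5758293035489004
        se = np.sqrt(1 / 20 - 1 / 100 + 1 / 10 - 1 / 100)
        assert res.ci99[0] == pytest.approx(2.0 * np.exp(-z * se), rel=1e-6)
        assert res.ci99[1] == pytest.approx(2.0 * np.exp(z * se), rel=1e-6)

    def test_zero_numerator_continuity_corrected(self):
        res = relative_risk(5, 50, 0, 50)
        assert res.corrected
        assert np.isfinite(res.rr) and res.rr > 1

    def test_group_against_itself_is_exactly_one(self):
        res = relative_risk(7, 30, 7, 30)
        assert res.rr == 1.0


class TestBaselineCompare:
    def test_levels_equal_baseline_degenerate(self):
        stable = {"s1": [5.0, 5.0], "s2": [5.0]}
        levels = {"s1": [5.0], "s2": [5.0]}
        baseline, res = baseline_compare(levels, stable, n_iter=10,
                                         rng=np.random.default_rng(0))
        assert baseline == 5.0
        assert res.median_p == 1.0

    def test_uniform_positive_offset_detected(self):
        # all levels sit above baseline; exact one-sided null gives p = 2^-n
        stable = {f"s{i}": [1.0] for i in range(12)}
        levels = {f"s{i}": [1.0 + 0.1] for i in range(12)}
        baseline, res = baseline_compare(levels, stable, alternative="greater",
                                         n_iter=10, rng=np.random.default_rng(0))
        assert res.median_p == pytest.approx(0.5**12, rel=1e-9)

    def test_plain_one_sample_variant(self):
        stable = {"s1": [2.0], "s2": [2.0]}
        levels = {"s1": [2.5, 2.6], "s2": [2.4]}
        baseline, res = baseline_compare(levels, stable, iterate=False,
                                         alternative="greater")
        direct = sps.wilcoxon([0.5, 0.6, 0.4], alternative="greater").pvalue
        assert res.median_p == pytest.approx(direct)


class TestCorrelation:
    def test_exactly_linear_gives_unit_rho(self):
        d = np.arange(10.0)
        rho, _ = magnitude_delay_correlation(2.0 * d + 1.0, d)
        assert rho == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(5)
        rho, _ = magnitude_delay_correlation(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(rho) < 0.1

    def test_anticorrelated_is_negative(self):
        d = np.arange(20.0)
        rng = np.random.default_rng(6)
        rho, _ = magnitude_delay_correlation(-d + rng.normal(0, 0.5, 20), d)
        assert rho < 0

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            magnitude_delay_correlation(np.ones(5), np.arange(5.0))


class TestSignedRank:
    def test_all_zero_differences_give_p_one(self):
        assert signed_rank_p(np.zeros(10)) == 1.0

    def test_exact_small_sample_matches_scipy(self):
        d = np.array([0.3, -0.1, 0.5, 0.2, -0.4, 0.6, 0.1, -0.2])
        assert signed_rank_p(d) == pytest.approx(
            sps.wilcoxon(d, method="exact").pvalue
        )

    def test_zeros_fall_back_to_pratt_normal(self):
        d = np.array([0.0, 0.1, 0.2, -0.1, 0.3, 0.0, 0.4, 0.1, 0.2, -0.3])
        expected = sps.wilcoxon(d, zero_method="pratt", method="approx",
                                correction=True).pvalue
        assert signed_rank_p(d) == pytest.approx(expected)
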