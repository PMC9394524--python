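"""Inference procedures: sliding ANOVA, FDR, KS, bootstrap, orientation."""

import numpy as np
import pytest

from polarcap import (
    bootstrap_ci,
    cosine_of_orientation,
    diff_means_bootstrap,
    fdr_adjust,
    ks_two_sample,
    phenotype_frequency,
    sliding_anova,
)
from polarcap.errors import (
    InvalidInputError,
    UndefinedOrientationError,
)

from oracles import bh_stepup, brute_ks_statistic, oneway_anova_f


class TestSlidingAnova:
    def test_f_matches_textbook_formula_on_toy_table(self):
        groups = [
            np.array([[1.0], [2.0], [3.0]]),
            np.array([[2.0], [4.0], [6.0]]),
            np.array([[5.0], [7.0], [9.0]]),
        ]
        res = sliding_anova(groups, tukey=False)
        expected = oneway_anova_f([g[:, 0] for g in groups])
        assert res.f_stat[0] == pytest.approx(expected, rel=1e-12)

    def test_extreme_effect_flagged_everywhere(self, rng):
        a = rng.normal(0, 1, (20, 30))
        b = rng.normal(10, 1, (20, 30))  # huge constant shift
        res = sliding_anova([a, b])
        assert np.all(res.significant)
        assert np.all(res.tukey_q[0] < 0.05)

    def test_null_data_rarely_flagged(self, rng):
        a = rng.normal(0, 1, (30, 50))
        b = rng.normal(0, 1, (30, 50))
        c = rng.normal(0, 1, (30, 50))
        res = sliding_anova([a, b, c], tukey=False)
        assert res.significant.mean() <= 0.05

    def test_zero_variance_position_flagged_undefined(self):
        a = np.ones((5, 3))
        b = np.ones((5, 3))
        a[:, 2] = np.arange(5)
        b[:, 2] = np.arange(5) + 5
        res = sliding_anova([a, b], tukey=False)
        assert res.undefined[0] and res.undefined[1] and not res.undefined[2]
        assert np.isnan(res.p_raw[0])

    def test_input_validation(self):
        with pytest.raises(InvalidInputError):
            sliding_anova([np.ones((5, 3))])
        with pytest.raises(InvalidInputError):
            sliding_anova([np.ones((1, 3)), np.ones((5, 3))])


class TestFdrAdjust:
    def test_hand_step_up_example(self):
        q = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_trivial_cases(self):
        assert fdr_adjust(np.array([0.3]))[0] == pytest.approx(0.3)
        np.testing.assert_allclose(fdr_adjust(np.ones(7)), 1.0)

    def test_matches_stepup_oracle_and_monotone(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(2, 60))
            q = fdr_adjust(p)
            np.testing.assert_allclose(q, bh_stepup(p), atol=1e-12)
            assert np.all(q >= p - 1e-15)  # never decreases a p-value
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-15)  # preserves ranking

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            fdr_adjust(np.array([0.5, 1.2]))


class TestKsTwoSample:
    def test_identical_and_disjoint_samples(self):
        d, _ = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0
        d, p = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    def test_symmetric_and_monotone_invariant(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 30)
        d1, _ = ks_two_sample(a, b)
        d2, _ = ks_two_sample(b, a)
        assert d1 == d2
        d3, _ = ks_two_sample(np.exp(a), np.exp(b))  # common monotone transform
        assert d3 == pytest.approx(d1, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(2, 50))
            b = rng.normal(rng.uniform(-1, 1), 1, rng.integers(2, 50))
            d, _ = ks_two_sample(a, b)
            assert d == pytest.approx(brute_ks_statistic(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            ks_two_sample([], [1.0])


class TestBootstrapCI:
    def test_all_equal_sample_zero_width(self):
        ci = bootstrap_ci(np.full(10, 3.0), n_boot=100, seed=0)
        assert ci.lower == ci.upper == ci.estimate == 3.0

    def test_seed_reproducible(self, rng):
        x = rng.normal(0, 1, 25)
        a = bootstrap_ci(x, n_boot=500, seed=99)
        b = bootstrap_ci(x, n_boot=500, seed=99)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_brackets_estimate(self, rng):
        x = rng.normal(5, 2, 40)
        ci = bootstrap_ci(x, n_boot=1000, seed=1)
        assert ci.lower <= ci.estimate <= ci.upper

    def test_tiny_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            bootstrap_ci(np.array([1.0]))


class TestDiffMeansBootstrap:
    def test_identical_constants_not_significant(self):
        ci, sig = diff_means_bootstrap(np.full(5, 2.0), np.full(5, 2.0), n_boot=200, seed=0)
        assert ci.lower == ci.upper == 0.0
        assert not sig

    def test_separated_samples_significant(self, rng):
        a = rng.normal(1, 0.1, 50)
        b = rng.normal(0, 0.1, 50)
        ci, sig = diff_means_bootstrap(a, b, n_boot=1000, seed=0)
        assert sig and ci.lower > 0

    def test_seed_reproducible(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        r1 = diff_means_bootstrap(a, b, n_boot=300, seed=5)
        r2 = diff_means_bootstrap(a, b, n_boot=300, seed=5)
        assert (r1[0].lower, r1[0].upper) == (r2[0].lower, r2[0].upper)


class TestPhenotypeFrequency:
    def test_boundary_counts(self):
        lo = phenotype_frequency(0, 50, n_boot=500, seed=0)
        assert lo.estimate == 0.0 and lo.lower == 0.0
        hi = phenotype_frequency(50, 50, n_boot=500, seed=0)
        assert hi.estimate == 1.0 and hi.upper == 1.0

    def test_close_to_analytic_binomial_interval(self):
        """Bootstrap CI for k=30/n=100 agrees with the Clopper-Pearson and
        normal-approximation intervals within 0.03."""
        from statsmodels.stats.proportion import proportion_confint

        ci = phenotype_frequency(30, 100, n_boot=20000, seed=0)
        for method in ("beta", "normal"):
            lo, hi = proportion_confint(30, 100, alpha=0.05, method=method)
            assert ci.lower == pytest.approx(lo, abs=0.03)
            assert ci.upper == pytest.approx(hi, abs=0.03)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            phenotype_frequency(5, 0)
        with pytest.raises(InvalidInputError):
            phenotype_frequency(7, 5)


class TestCosineOfOrientation:
    @pytest.mark.parametrize(
        "vec,expected",
        [((2.0, 0.0), 1.0), ((0.0, 3.0), 0.0), ((-1.5, 0.0), -1.0)],
    )
    def test_parallel_perpendicular_antiparallel(self, vec, expected):
        rec = cosine_of_orientation(np.array(vec), np.array([1.0, 0.0]))
        assert rec.cosine == pytest.approx(expected, abs=1e-12)

    def test_zero_displacement_rejected(self):
        with pytest.raises(UndefinedOrientationError):
            cosine_of_orientation(np.zeros(2), np.array([1.0, 0.0]))

    def test_unnormalized_gradient_axis_ok(self):
        rec = cosine_of_orientation(np.array([1.0, 1.0]), np.array([10.0, 0.0]))
        assert rec.cosine == pytest.approx(np.sqrt(0.5))
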