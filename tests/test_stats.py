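"""Permutation tests, multiplicity corrections, CV, RM-ANOVA, regressions."""

import itertools

import numpy as np
import pytest

from meginet.stats import (
    benjamini_hochberg,
    coefficient_of_variation,
    entropy_strength_fit,
    fda_permutation_test,
    holm_bonferroni,
    permutation_test,
    rm_anova_cv,
)


class TestPermutationTest:
    def test_identical_samples_give_one(self):
        a = np.array([1.0, 2.0, 3.0])
        assert permutation_test(a, a.copy(), n_perm=200, seed=0) == 1.0

    def test_fully_separated_groups_reach_minimum_p(self, rng):
        a = rng.normal(0, 1, 14)
        b = rng.normal(20, 1, 14)
        p = permutation_test(a, b, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_exhaustive_check_at_n4(self, rng):
        # brute-force oracle: enumerate all label assignments
        a = rng.normal(0, 1, 4)
        b = rng.normal(0.8, 1, 4)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = sum(
            abs(pooled[list(idx)].mean()
                - np.delete(pooled, list(idx)).mean()) >= obs - 1e-12
            for idx in itertools.combinations(range(8), 4)
        )
        exact = count / 70
        p = permutation_test(a, b, n_perm=20000, seed=3)
        assert p == pytest.approx(exact, abs=0.02)

    def test_label_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        assert permutation_test(a, b, 500, seed=7) == permutation_test(
            b, a, 500, seed=7
        )


class TestCorrections:
    def test_holm_two_values(self):
        np.testing.assert_allclose(
            holm_bonferroni([0.01, 0.04]), [0.02, 0.04]
        )

    def test_holm_single_and_ceiling(self):
        assert holm_bonferroni([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(holm_bonferroni([1.0, 1.0, 1.0]), 1.0)

    def test_holm_matches_bruteforce_definition(self, rng):
        for _ in range(6):
            p = rng.uniform(0.001, 1.0, size=rng.integers(2, 7))
            order = np.argsort(p)
            m = p.size
            adj_sorted = np.maximum.accumulate(
                [min(1.0, (m - j) * p[order][j]) for j in range(m)]
            )
            expected = np.empty_like(p)
            expected[order] = adj_sorted
            np.testing.assert_allclose(holm_bonferroni(p), expected)

    def test_bh_flags_forced_cases(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04], q=0.05).all()
        assert not benjamini_hochberg([0.9, 0.95], q=0.05).any()

    def test_bh_matches_bruteforce_stepup(self, rng):
        for _ in range(6):
            p = rng.uniform(0.001, 1.0, size=6)
            order = np.argsort(p)
            ps = p[order]
            ks = [k for k in range(1, 7) if ps[k - 1] <= k * 0.05 / 6]
            expected = np.zeros(6, dtype=bool)
            if ks:
                expected[p <= ps[max(ks) - 1]] = True
            np.testing.assert_array_equal(
                benjamini_hochberg(p, q=0.05), expected
            )

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.0, 0.5])


class TestFDA:
    def test_label_swap_symmetry(self, rng):
        a = rng.normal(0, 1, (5, 20))
        b = rng.normal(0.3, 1, (5, 20))
        assert fda_permutation_test(a, b, 500, seed=2) == fda_permutation_test(
            b, a, 500, seed=2
        )

    def test_shifted_curves_detected(self, rng):
        a = rng.normal(0, 0.5, (10, 30))
        b = rng.normal(0, 0.5, (10, 30)) + 3.0
        assert fda_permutation_test(a, b, 999, seed=0) == pytest.approx(1 / 1000)

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            a = rng.normal(0, 1, (6, 10))
            b = rng.normal(0, 1, (6, 10))
            ps.append(fda_permutation_test(a, b, 99, seed=int(rng.integers(1 << 30))))
        rate = np.mean(np.asarray(ps) <= 0.05)
        assert 0.01 <= rate <= 0.10  # binomial 95% band around 0.05

    def test_missing_grid_points_dropped_pairwise(self, rng):
        a = rng.normal(0, 1, (5, 10))
        b = rng.normal(0, 1, (5, 10))
        a2 = a.copy()
        a2[:, 3] = np.nan  # entire column missing in one group
        p1 = fda_permutation_test(np.delete(a, 3, 1), np.delete(b, 3, 1), 200, 5)
        p2 = fda_permutation_test(a2, b, 200, 5)
        assert p1 == p2

    def test_sup_statistic_option(self, rng):
        a = rng.normal(0, 1, (5, 10))
        b = rng.normal(0, 1, (5, 10))
        p = fda_permutation_test(a, b, 200, seed=1, statistic="sup")
        assert 0 < p <= 1


class TestCV:
    def test_constant_values_zero(self):
        assert coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0

    def test_hand_computation(self):
        assert coefficient_of_variation([2.0, 4.0]) == pytest.approx(
            np.sqrt(2) / 3
        )

    def test_scale_invariance(self, rng):
        v = rng.random(10) + 0.5
        assert coefficient_of_variation(7.0 * v) == pytest.approx(
            coefficient_of_variation(v)
        )

    def test_zero_mean_missing(self):
        assert np.isnan(coefficient_of_variation([-1.0, 1.0]))


class TestRMAnova:
    def _fixture(self):
        rng = np.random.default_rng(42)
        n_s, n_b, n_d = 6, 3, 4
        y = (
            rng.normal(size=(n_s, n_b, n_d))
            + 0.5 * np.arange(n_d)
            + np.repeat([0, 0.8], 3)[:, None, None]
        )
        return y, np.array(["c", "c", "c", "p", "p", "p"])

    def test_matches_r_aov_oracle(self):
        # reference F values computed with R: aov(y ~ group*band*diag +
        # Error(subject/(band*diag))) on this exact seeded fixture
        y, groups = self._fixture()
        res = rm_anova_cv(y, groups)
        expected_f = {
            "group": 23.148987,
            "band": 0.200094,
            "diagnostic": 35.058412,
            "band*diagnostic": 0.360628,
            "band*group": 0.056017,
            "diagnostic*group": 8.111284,
            "band*diagnostic*group": 1.077557,
        }
        for effect, f in expected_f.items():
            assert res.effect(effect)["F"] == pytest.approx(f, rel=1e-5)

    def test_design_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(8, 10, 10))
        groups = ["a"] * 4 + ["b"] * 4
        t = rm_anova_cv(y, groups).table.set_index("effect")["DF"]
        assert t["group"] == 1
        assert t["band"] == 9
        assert t["diagnostic"] == 9
        assert t["band*diagnostic"] == 81
        assert t["band*group"] == 9
        assert t["diagnostic*group"] == 9
        assert t["band*diagnostic*group"] == 81

    def test_null_group_f_near_one(self):
        rng = np.random.default_rng(1)
        fs = []
        for _ in range(100):
            y = rng.normal(size=(8, 4, 5))
            fs.append(
                rm_anova_cv(y, ["a"] * 4 + ["b"] * 4).effect("group")["F"]
            )
        # F(1, 6) has mean df2/(df2-2) = 1.5
        se = np.std(fs, ddof=1) / 10
        assert abs(np.mean(fs) - 1.5) < 3 * se

    def test_injected_group_effect_detected(self):
        from scipy.stats import f as fdist

        rng = np.random.default_rng(2)
        crit = fdist.ppf(0.95, 1, 10)
        hits = 0
        for _ in range(50):
            y = rng.normal(size=(12, 4, 5), scale=0.3)
            y[6:] += 0.5
            hits += rm_anova_cv(y, ["a"] * 6 + ["b"] * 6).effect("group")["F"] > crit
        assert hits >= 40

    def test_missing_cells_rejected(self):
        y = np.random.default_rng(0).normal(size=(4, 3, 3))
        y[1, 2, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_cv(y, ["a", "a", "b", "b"])


class TestEntropyStrengthFit:
    def test_collinear_points_give_unit_r2(self):
        x = np.arange(5.0)
        fit = entropy_strength_fit(x, 2.0 - 0.3 * x)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-0.3)

    def test_independent_noise_r2_matches_null_distribution(self, rng):
        # exact null at n=14: R^2 < 0.2 iff |r| < 0.4472, i.e. |t| < 1.731
        # on 12 df, so P(R^2 < 0.2) = 0.8906; check within 3 binomial SD
        from scipy.stats import t as tdist

        n = 14
        t_crit = np.sqrt(0.2 * (n - 2) / 0.8)
        p_low = 1 - 2 * tdist.sf(t_crit, n - 2)
        low = 0
        n_rep = 100
        for _ in range(n_rep):
            fit = entropy_strength_fit(rng.normal(size=n), rng.normal(size=n))
            low += fit.r_squared < 0.2
        sd = np.sqrt(n_rep * p_low * (1 - p_low))
        assert abs(low - n_rep * p_low) <= 3 * sd

    def test_zero_variance_entropy_missing_slope(self):
        fit = entropy_strength_fit(np.ones(5), np.arange(5.0))
        assert np.isnan(fit.slope)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            entropy_strength_fit([1.0, 2.0], [1.0, 2.0])
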