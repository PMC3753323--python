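"""Histogram MI, Strehl-Ghosh NMI, and connectivity matrix assembly."""

import itertools

import numpy as np
import pytest

from meginet.connectivity import (
    NETWORK_KINDS,
    build_inter_matrix,
    build_intra_matrix,
    histogram_mi,
    normalized_mi,
    pairwise_nmi,
    strength,
    trial_matrices,
)


class TestHistogramMI:
    def test_self_information_identity(self, rng):
        x = rng.normal(size=216)
        i, hx, hy = histogram_mi(x, x)
        assert i == pytest.approx(hx, abs=1e-12)
        assert hx == hy

    def test_independent_noise_below_permutation_null(self, rng):
        hits = 0
        for _ in range(200):
            x, y = rng.normal(size=(2, 216))
            i, _, _ = histogram_mi(x, y)
            null = [
                histogram_mi(x, rng.permutation(y))[0] for _ in range(19)
            ]
            hits += i <= np.quantile(null, 0.95)
        assert hits >= 0.9 * 200 * 0.8  # well above chance-only agreement

    def test_quantile_bins_invariant_to_monotone_transform(self, rng):
        x, y = rng.normal(size=(2, 216))
        i1, _, _ = histogram_mi(x, y, binning="quantile")
        i2, _, _ = histogram_mi(np.exp(x) + 5.0, y, binning="quantile")
        assert abs(i1 - i2) < 1e-9

    def test_constant_series_flagged_and_zero(self):
        x = np.ones(216)
        y = np.arange(216.0)
        with pytest.warns(UserWarning, match="constant series"):
            i, hx, _ = histogram_mi(x, y)
        assert i == 0.0 and hx == 0.0

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            histogram_mi(rng.normal(size=8), rng.normal(size=8))


class TestNormalizedMI:
    def test_identical_series_give_one(self, rng):
        x = rng.normal(size=216)
        assert normalized_mi(x, x) == pytest.approx(1.0)

    def test_independent_noise_stays_below_bias_bound(self, rng):
        vals = [
            normalized_mi(*rng.normal(size=(2, 216))) for _ in range(100)
        ]
        assert np.mean(vals) < 0.15

    def test_bounded_unit_interval(self, rng):
        for _ in range(50):
            x, y = rng.normal(size=(2, 216))
            assert 0.0 <= normalized_mi(x, y) <= 1.0

    def test_pairwise_matches_scalar_loop(self, rng):
        x = rng.normal(size=(5, 216))
        y = rng.normal(size=(4, 216))
        m = pairwise_nmi(x)
        for i, j in itertools.product(range(5), range(5)):
            assert m[i, j] == pytest.approx(
                normalized_mi(x[i], x[j]), abs=1e-12
            )
        mxy = pairwise_nmi(x, y)
        for i, j in itertools.product(range(5), range(4)):
            assert mxy[i, j] == pytest.approx(
                normalized_mi(x[i], y[j]), abs=1e-12
            )


class TestMatrices:
    def test_ten_kinds_per_trial(self, small_decomp):
        mats = trial_matrices(small_decomp, trial=0)
        assert set(mats) == set(NETWORK_KINDS)
        assert len([k for k in mats if k.startswith("intra")]) == 4
        assert len([k for k in mats if k.startswith("inter")]) == 6

    def test_660_matrices_per_subject_at_full_protocol(self):
        # 10 kinds per trial x 66 trials
        assert len(NETWORK_KINDS) * 66 == 660

    def test_intra_symmetric_zero_diagonal_unit_range(self, small_decomp):
        m = build_intra_matrix(small_decomp, "alpha", 1)
        w = m.weights
        np.testing.assert_array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        assert w.min() >= 0 and w.max() <= 1

    def test_duplicate_sensor_yields_unit_weight(self, small_decomp):
        import copy

        dup = copy.copy(small_decomp)
        dup.coefficients = {
            k: v.copy() for k, v in small_decomp.coefficients.items()
        }
        dup.coefficients["alpha"][3] = dup.coefficients["alpha"][5]
        m = build_intra_matrix(dup, "alpha", 0)
        assert m.weights[3, 5] == pytest.approx(1.0)

    def test_inter_matrix_symmetrized_with_raw_kept(self, small_decomp):
        m = build_inter_matrix(small_decomp, "theta", "gamma_low", 0)
        np.testing.assert_array_equal(m.weights, m.weights.T)
        assert m.raw is not None
        off = ~np.eye(m.n_sensors, dtype=bool)
        np.testing.assert_allclose(
            m.weights[off], ((m.raw + m.raw.T) / 2)[off], atol=1e-12
        )

    def test_same_band_pair_rejected(self, small_decomp):
        with pytest.raises(ValueError):
            build_inter_matrix(small_decomp, "beta", "beta", 0)


class TestStrength:
    def test_constant_matrix(self):
        w = np.full((5, 5), 0.3)
        np.fill_diagonal(w, 0.0)
        sp = strength(w)
        np.testing.assert_allclose(sp.sensor_strength, 0.3)
        assert sp.network_strength == pytest.approx(0.3)

    def test_three_node_hand_computation(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = 0.4
        w[1, 2] = w[2, 1] = 0.6
        sp = strength(w)
        np.testing.assert_allclose(sp.sensor_strength, [0.3, 0.4, 0.5])
        assert sp.network_strength == pytest.approx(0.4)

    def test_permutation_equivariance(self, rng):
        w = rng.random((6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        perm = rng.permutation(6)
        sp = strength(w)
        sp_p = strength(w[np.ix_(perm, perm)])
        np.testing.assert_allclose(sp_p.sensor_strength, sp.sensor_strength[perm])
        assert sp_p.network_strength == pytest.approx(sp.network_strength)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            strength(np.zeros((1, 1)))
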