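"""Cross-correlation, DTW (vs a brute-force oracle) and non-negative attribution."""

from functools import lru_cache

import numpy as np
import pytest

from fnirsim.attribution import (
    attribute_compartments,
    cross_correlate,
    dtw_compare,
    pearson_correlation,
    rescale_to_range,
)


def dtw_oracle_distance(x, y):
    """Independent exhaustive DP oracle: memoised recursion over the same
    symmetric step pattern (diagonal/up/left, |a-b| local cost)."""
    x = tuple(float(v) for v in x)
    y = tuple(float(v) for v in y)

    @lru_cache(maxsize=None)
    def d(i, j):
        cost = abs(x[i] - y[j])
        if i == 0 and j == 0:
            return cost
        options = []
        if i > 0 and j > 0:
            options.append(d(i - 1, j - 1))
        if i > 0:
            options.append(d(i - 1, j))
        if j > 0:
            options.append(d(i, j - 1))
        return cost + min(options)

    return d(len(x) - 1, len(y) - 1)


class TestCrossCorrelation:
    def test_self_correlation_peaks_at_lag_zero_with_value_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        res = cross_correlate(x, x, dt=1.0, max_lag=150.0)
        assert res.max_correlation == pytest.approx(1.0, abs=1e-12)
        assert res.lag_at_max == 0.0

    def test_delayed_sinusoid_recovers_the_shift(self):
        t = np.arange(0.0, 600.0)
        x = np.sin(2 * np.pi * t / 120.0)
        y = np.sin(2 * np.pi * (t - 30.0) / 120.0)  # y lags x by 30 s
        res = cross_correlate(x, y, dt=1.0, max_lag=150.0)
        assert res.lag_at_max == pytest.approx(-30.0, abs=1.0)
        assert res.max_correlation > 0.9

    def test_white_noise_pair_has_small_maximum(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(20):
            x = rng.standard_normal(200)
            y = rng.standard_normal(200)
            res = cross_correlate(x, y, dt=1.0, max_lag=30.0)
            hits += abs(res.max_correlation) < 0.3
        assert hits >= 18  # high probability bound

    def test_lag_range_respects_maximum(self):
        res = cross_correlate(np.sin(np.arange(100.0)), np.cos(np.arange(100.0)),
                              dt=2.0, max_lag=20.0)
        assert np.max(np.abs(res.lags)) <= 20.0

    def test_pearson_is_lag_zero_case(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        res = cross_correlate(x, y, dt=1.0, max_lag=10.0)
        lag0 = res.correlation[np.where(res.lags == 0.0)[0][0]]
        assert lag0 == pytest.approx(pearson_correlation(x, y), abs=1e-12)


class TestRescale:
    def test_in_range_model_is_identity_at_extremes(self):
        measured = np.array([0.0, 1.0, 2.0, 3.0])
        model = np.array([0.0, 2.5, 1.0, 3.0])
        out = rescale_to_range(model, measured)
        assert out.min() == pytest.approx(measured.min())
        assert out.max() == pytest.approx(measured.max())

    def test_scaled_copy_maps_back_exactly(self):
        measured = np.sin(np.arange(50.0) / 5.0)
        out = rescale_to_range(2.0 * measured, measured)
        np.testing.assert_allclose(out, measured, atol=1e-12)

    def test_arbitrary_pair_hits_measured_extremes(self):
        rng = np.random.default_rng(5)
        measured = rng.standard_normal(40)
        model = 3.0 + 10.0 * rng.standard_normal(40)
        out = rescale_to_range(model, measured)
        assert out.min() == pytest.approx(measured.min(), abs=1e-12)
        assert out.max() == pytest.approx(measured.max(), abs=1e-12)

    def test_constant_measured_rejected(self):
        with pytest.raises(ValueError):
            rescale_to_range(np.arange(5.0), np.ones(5))


class TestDTW:
    def test_identical_series_give_zero_warp_and_distance(self):
        x = np.sin(np.arange(30.0) / 3.0)
        res = dtw_compare(x, x.copy())
        assert res.warp == 0.0
        assert res.distance == 0.0

    def test_shifted_step_warps_with_near_zero_distance(self):
        x = np.zeros(30)
        x[10:] = 1.0
        y = np.zeros(30)
        y[15:] = 1.0  # same step, 5 samples later
        res = dtw_compare(x, y)
        assert res.warp > 0.0
        assert res.distance == pytest.approx(0.0, abs=1e-12)

    def test_distance_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            res = dtw_compare(x, y)
            assert res.distance == pytest.approx(dtw_oracle_distance(x, y), abs=1e-12)

    def test_diagonal_path_reduces_to_pointwise_distance(self):
        """When the optimal path is the diagonal, D equals the accumulated
        unwarped pointwise distance."""
        x = np.linspace(0.0, 1.0, 15)
        y = x + 1e-3  # tiny uniform offset keeps the diagonal optimal
        res = dtw_compare(x, y)
        assert res.warp == 0.0
        assert res.distance == pytest.approx(np.sum(np.abs(x - y)), rel=1e-9)


class TestAttribution:
    @staticmethod
    def model_signals(n=200):
        t = np.arange(float(n))
        cer_hbo2 = np.sin(2 * np.pi * t / 80.0)
        cer_hhb = -0.3 * np.sin(2 * np.pi * t / 80.0 + 0.3)
        sca_hbo2 = 0.8 * np.sin(2 * np.pi * t / 37.0)
        sca_hhb = 0.4 * np.sin(2 * np.pi * t / 37.0 + 0.1)
        return cer_hbo2, cer_hhb, sca_hbo2, sca_hhb

    def test_noiseless_mixture_recovered_exactly(self):
        c1, c2, s1, s2 = self.model_signals()
        meas1 = 0.3 * s1 + 0.7 * c1
        meas2 = 0.3 * s2 + 0.7 * c2
        fit = attribute_compartments(meas1, meas2, c1, c2, s1, s2)
        assert fit.w_scalp == pytest.approx(0.3, abs=1e-6)
        assert fit.w_cerebral == pytest.approx(0.7, abs=1e-6)
        assert fit.residual == pytest.approx(0.0, abs=1e-9)

    def test_pure_scalp_measurement_gives_zero_cerebral_weight(self):
        c1, c2, s1, s2 = self.model_signals()
        fit = attribute_compartments(s1, s2, c1, c2, s1, s2)
        assert fit.w_scalp == pytest.approx(1.0, abs=1e-9)
        assert fit.w_cerebral == pytest.approx(0.0, abs=1e-9)

    def test_anti_correlated_measurement_binds_non_negativity(self):
        c1, c2, s1, s2 = self.model_signals()
        fit = attribute_compartments(-s1, -s2, c1, c2, s1, s2)
        assert fit.w_scalp == 0.0
        norm = np.linalg.norm(np.concatenate([-s1 - fit.w_cerebral * c1,
                                              -s2 - fit.w_cerebral * c2]))
        assert fit.residual == pytest.approx(norm, rel=1e-9)

    def test_two_compartment_residual_never_worse_than_single(self):
        rng = np.random.default_rng(9)
        c1, c2, s1, s2 = self.model_signals()
        meas1 = 0.4 * s1 + 0.5 * c1 + 0.05 * rng.standard_normal(c1.size)
        meas2 = 0.4 * s2 + 0.5 * c2 + 0.05 * rng.standard_normal(c2.size)
        joint = attribute_compartments(meas1, meas2, c1, c2, s1, s2)
        zeros = np.zeros_like(c1)
        only_scalp = attribute_compartments(meas1, meas2, zeros + 1e-9, zeros, s1, s2)
        only_cer = attribute_compartments(meas1, meas2, c1, c2, zeros + 1e-9, zeros)
        assert joint.residual <= only_scalp.residual + 1e-12
        assert joint.residual <= only_cer.residual + 1e-12

    def test_degenerate_model_signals_rejected(self):
        c1, c2, s1, s2 = self.model_signals()
        with pytest.raises(ValueError, match="collinear"):
            attribute_compartments(c1, c2, c1, c2, 2.0 * c1, 2.0 * c2)
        with pytest.raises(ValueError, match="norm"):
            attribute_compartments(c1, c2, c1, c2, 0.0 * c1, 0.0 * c2)

    def test_weights_unbiased_under_noise_and_rmse_shrinks_with_n(self):
        """Gaussian noise at 10% of signal range: the recovered weights are
        unbiased within Monte-Carlo error over 100 replicates, and the RMSE
        decreases as the series length grows."""
        rng = np.random.default_rng(2024)
        true_s, true_c = 0.3, 0.7

        def run(n, replicates=100):
            c1, c2, s1, s2 = self.model_signals(n)
            meas1 = true_s * s1 + true_c * c1
            meas2 = true_s * s2 + true_c * c2
            sd1 = 0.10 * np.ptp(meas1)
            sd2 = 0.10 * np.ptp(meas2)
            est = np.empty((replicates, 2))
            for k in range(replicates):
                fit = attribute_compartments(
                    meas1 + sd1 * rng.standard_normal(n),
                    meas2 + sd2 * rng.standard_normal(n),
                    c1, c2, s1, s2,
                )
                est[k] = fit.w_scalp, fit.w_cerebral
            return est

        est = run(200)
        for j, true in enumerate((true_s, true_c)):
            se = est[:, j].std(ddof=1) / np.sqrt(len(est))
            assert abs(est[:, j].mean() - true) < 4.0 * se + 1e-3
        rmse = {
            n: np.sqrt(np.mean((run(n, 60) - [true_s, true_c]) ** 2)) for n in (50, 400)
        }
        assert rmse[400] < rmse[50]
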