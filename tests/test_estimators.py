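import numpy as np
import pytest
from scipy import stats

from mrpath import (LDInfo, egger_regression, f_statistic, ivw,
                    ivw_correlated, mode_based_estimate, to_odds_ratio,
                    wald_ratio, weighted_median)
from mrpath.estimators import (DegenerateInstrumentError,
                               InsufficientInstrumentsError)

from conftest import make_harmonized


class TestWaldRatio:
    def test_direct_arithmetic(self):
        r = wald_ratio(0.1, 0.01, 0.05, 0.02, "first")
        assert r.theta == pytest.approx(0.5)
        assert r.se_theta == pytest.approx(0.2)

    def test_null_numerator(self):
        r = wald_ratio(1.0, 0.1, 0.0, 0.1, "first")
        assert r.theta == 0.0 and r.se_theta == pytest.approx(0.1)

    def test_zero_denominator_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    def test_second_order_se_matches_monte_carlo(self):
        """Delta-method SE vs the empirical SD of the simulated ratio."""
        bx, sx, by, sy = 0.1, 0.005, 0.05, 0.002
        r = wald_ratio(bx, sx, by, sy, "second")
        rng = np.random.default_rng(0)
        n = 400_000
        sim = rng.normal(by, sy, n) / rng.normal(bx, sx, n)
        assert r.se_theta == pytest.approx(sim.std(), rel=0.02)


class TestFStatistic:
    @pytest.mark.parametrize("b,s,expected", [(0.1, 0.01, 100.0),
                                              (0.02, 0.02, 1.0)])
    def test_arithmetic(self, b, s, expected):
        assert f_statistic(b, s) == pytest.approx(expected)

    def test_equals_squared_t_of_regression_slope(self):
        rng = np.random.default_rng(5)
        n = 10_000
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.08 * g + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), g])
        coef, rss, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sigma2 = resid @ resid / (n - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t2 = (coef[1] / se) ** 2
        assert f_statistic(coef[1], se) == pytest.approx(t2, rel=1e-10)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)


class TestIVW:
    def test_equal_weight_pooling(self):
        h = make_harmonized([0.1, 0.1], [0.001, 0.001], [0.05, 0.05],
                            [0.02, 0.02])
        e = ivw(h, "fixed")
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.2 / np.sqrt(2), rel=1e-12)

    def test_matches_origin_constrained_wls(self, noisy_h):
        e = ivw(noisy_h, "fixed")
        w = 1.0 / noisy_h.se_gy**2
        wls = np.sum(w * noisy_h.beta_gx * noisy_h.beta_gy) / \
            np.sum(w * noisy_h.beta_gx**2)
        assert e.beta == pytest.approx(wls, abs=1e-12)

    def test_random_effects_floor(self, homogeneous_h):
        assert ivw(homogeneous_h, "random").se == \
            pytest.approx(ivw(homogeneous_h, "fixed").se)

    def test_random_effects_inflation(self, noisy_h):
        h = noisy_h
        # inject heterogeneity
        h = make_harmonized(h.beta_gx, h.se_gx,
                            h.beta_gy + np.linspace(-0.01, 0.01, h.n_snps),
                            h.se_gy)
        fixed, random = ivw(h, "fixed"), ivw(h, "random")
        q = fixed.heterogeneity.Q
        assert q > h.n_snps - 1
        assert random.se == pytest.approx(
            fixed.se * np.sqrt(q / (h.n_snps - 1)), rel=1e-10)

    def test_insufficient_instruments(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)


class TestEgger:
    def test_exact_fit_recovered(self):
        bx = np.linspace(0.02, 0.1, 10)
        h = make_harmonized(bx, np.full(10, 0.002), 0.01 + 0.8 * bx,
                            np.full(10, 0.01))
        e = egger_regression(h)
        assert e.slope.beta == pytest.approx(0.8, abs=1e-10)
        assert e.intercept == pytest.approx(0.01, abs=1e-10)
        assert e.slope.diagnostics["residual_scale"] == 1.0

    def test_constrained_intercept_equals_ivw(self, noisy_h):
        e = egger_regression(noisy_h, constrain_intercept=True)
        assert e.slope.beta == pytest.approx(ivw(noisy_h, "fixed").beta,
                                             abs=1e-12)

    def test_intercept_ci_contains_intercept(self, noisy_h):
        e = egger_regression(noisy_h)
        lo, hi = e.intercept_ci
        assert lo <= e.intercept <= hi
        assert 0.0 <= e.i2_gx <= 1.0

    def test_requires_three_instruments(self):
        h = make_harmonized([0.1, 0.2], [0.01, 0.01], [0.05, 0.1],
                            [0.02, 0.02])
        with pytest.raises(InsufficientInstrumentsError):
            egger_regression(h)


class TestWeightedMedian:
    def test_middle_ratio_equal_weights(self):
        h = make_harmonized([0.1, 0.1, 0.1], [0.001] * 3, [0.1, 0.2, 0.3],
                            [0.01] * 3)
        e = weighted_median(h, n_boot=100, seed=1)
        assert e.beta == pytest.approx(2.0)

    def test_degenerate_identical_ratios(self):
        h = make_harmonized([0.1] * 3, [0.0001] * 3, [0.05] * 3, [0.01] * 3)
        e = weighted_median(h, n_boot=100, seed=1)
        assert e.beta == pytest.approx(0.5, abs=1e-6)

    def test_resists_invalid_minority(self):
        """30% of weight pleiotropic: median near truth, IVW pulled away."""
        rng = np.random.default_rng(42)
        j = 60
        bx = rng.uniform(0.03, 0.08, j)
        by = 0.1 * bx
        by[:18] += 0.02  # directional pleiotropy on 30%
        se_gy = np.full(j, 0.002)
        h = make_harmonized(bx, np.full(j, 0.0005), by, se_gy)
        wm = weighted_median(h, n_boot=200, seed=3)
        naive = ivw(h, "fixed")
        assert abs(wm.beta - 0.1) < 0.05
        assert abs(naive.beta - 0.1) > 2 * abs(wm.beta - 0.1)

    def test_seed_reproducible(self, noisy_h):
        a = weighted_median(noisy_h, n_boot=100, seed=9)
        b = weighted_median(noisy_h, n_boot=100, seed=9)
        assert a.beta == b.beta and a.se == b.se


class TestModeBasedEstimate:
    def test_ignores_single_outlier(self):
        h = make_harmonized([0.1] * 4, [0.001] * 4,
                            [0.01, 0.0101, 0.0099, 0.5], [0.005] * 4)
        e = mode_based_estimate(h, n_boot=100, seed=1)
        assert e.beta == pytest.approx(0.1, abs=0.02)

    def test_bandwidth_scales_linearly_with_phi(self, noisy_h):
        e1 = mode_based_estimate(noisy_h, phi=1.0, n_boot=50, seed=1)
        e2 = mode_based_estimate(noisy_h, phi=2.0, n_boot=50, seed=1)
        assert e2.diagnostics["bandwidth"] == \
            pytest.approx(2 * e1.diagnostics["bandwidth"], rel=1e-12)

    def test_recovers_largest_cluster_when_median_fails(self):
        """60% of weight invalid but split; largest single cluster valid."""
        j = 50
        bx = np.full(j, 0.05)
        by = np.empty(j)
        by[:20] = 0.1 * 0.05            # valid cluster (40%)
        by[20:35] = 0.1 * 0.05 + 0.015  # pleiotropy group A
        by[35:] = 0.1 * 0.05 + 0.030    # pleiotropy group B
        rng = np.random.default_rng(0)
        by += rng.normal(0, 2e-4, j)
        h = make_harmonized(bx, np.full(j, 0.0005), by, np.full(j, 0.002))
        mbe = mode_based_estimate(h, n_boot=100, seed=2)
        wm = weighted_median(h, n_boot=100, seed=2)
        assert abs(mbe.beta - 0.1) < 0.05
        assert abs(wm.beta - 0.1) > abs(mbe.beta - 0.1)


class TestIVWCorrelated:
    def test_identity_ld_equals_ivw_fixed(self, noisy_h):
        ld = LDInfo(matrix=__import__("pandas").DataFrame(
            np.eye(noisy_h.n_snps), index=noisy_h.variant_ids,
            columns=noisy_h.variant_ids))
        e = ivw_correlated(noisy_h, ld)
        f = ivw(noisy_h, "fixed")
        assert e.beta == pytest.approx(f.beta, rel=1e-12)
        assert e.se == pytest.approx(f.se, rel=1e-12)

    def test_perfect_redundancy_equals_single_wald(self):
        import pandas as pd
        h = make_harmonized([0.1, 0.1], [0.01, 0.01], [0.05, 0.05],
                            [0.02, 0.02])
        ld = LDInfo(matrix=pd.DataFrame([[1.0, 1.0 - 1e-10], [1.0 - 1e-10, 1.0]],
                                        index=h.variant_ids, columns=h.variant_ids))
        e = ivw_correlated(h, ld)
        assert e.beta == pytest.approx(0.5, rel=1e-6)
        assert e.se == pytest.approx(0.2, rel=1e-4)

    def test_accounts_for_ld_widens_se(self):
        from mrpath import simulate_ld_blocks, simulate_two_sample, harmonize
        from mrpath import TwoSampleSimConfig
        ld = simulate_ld_blocks(10, 5, 0.3, seed=1)
        cfg = TwoSampleSimConfig(n_snps=50, theta=-0.1, seed=5,
                                 scramble_orientation=False)
        e, o, _ = simulate_two_sample(cfg, ld=ld)
        h = harmonize(e, o)
        naive = ivw(h, "fixed")
        adj = ivw_correlated(h, ld)
        assert adj.se > naive.se


class TestOddsRatioView:
    def test_exponentiation(self):
        e = ivw(make_harmonized([0.1, 0.1], [0.01, 0.01],
                                [-0.01744, -0.01744], [0.01, 0.01]))
        out = to_odds_ratio(e, "6.5 cm")
        assert out.odds_ratio == pytest.approx(np.exp(-0.1744), rel=1e-6)

    def test_null_is_multiplicatively_symmetric(self):
        e = ivw(make_harmonized([0.1, 0.1], [0.01, 0.01], [0.0, 0.0],
                                [0.01, 0.01]))
        out = to_odds_ratio(e)
        lo, hi = out.or_ci
        assert out.odds_ratio == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0, rel=1e-10)

    def test_quantitative_outcome_rejected(self, noisy_h):
        e = ivw(noisy_h)
        e.outcome_type = "quantitative"
        with pytest.raises(ValueError):
            to_odds_ratio(e)


class TestEstimatorProperties:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_exposure_rescaling_equivariance(self, noisy_h, c):
        h = noisy_h
        scaled = make_harmonized(c * h.beta_gx, c * h.se_gx, h.beta_gy, h.se_gy)
        for fn, kw in [(lambda x: ivw(x, "fixed"), {}),
                       (lambda x: egger_regression(x).slope, {}),
                       (lambda x: weighted_median(x, n_boot=200, seed=4), {}),
                       (lambda x: mode_based_estimate(x, n_boot=100, seed=4), {})]:
            a, b = fn(h), fn(scaled)
            assert b.beta == pytest.approx(a.beta / c, rel=1e-6), a.method
            assert b.se == pytest.approx(a.se / c, rel=0.15), a.method

    def test_ivw_equals_meta_analysis_of_wald_ratios(self, noisy_h):
        from mrpath import wald_ratios
        theta, se = wald_ratios(noisy_h, "first")
        w = 1 / se**2
        meta = np.sum(w * theta) / np.sum(w)
        assert ivw(noisy_h, "fixed").beta == pytest.approx(meta, abs=1e-14)
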