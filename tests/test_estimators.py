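"""Estimator correctness against closed forms and independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate import (
    CollinearityError,
    EstimationError,
    ivw,
    mode_estimate,
    mr_egger,
    mvmr_ivw,
    wald_ratio,
    weighted_median,
)
from mrmediate.estimators import MODE_GRID_POINTS, mode_bandwidth

from conftest import make_instruments


class TestWaldRatio:
    def test_first_order(self):
        h = make_instruments([0.5], [0.1], [0.05], [0.02])[0]
        est = wald_ratio(h)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)

    def test_unit_exposure_beta_is_identity(self):
        h = make_instruments([1.0], [0.07], [0.05], [0.02])[0]
        assert wald_ratio(h).beta == pytest.approx(0.07)

    def test_second_order_adds_exposure_uncertainty(self):
        h = make_instruments([0.5], [0.1], [0.05], [0.02])[0]
        est = wald_ratio(h, second_order=True)
        assert est.se == pytest.approx(np.sqrt(0.0016 + 0.0004))  # 0.044721...

    def test_zero_exposure_beta_rejected(self):
        h = make_instruments([0.0], [0.1])[0]
        with pytest.raises(EstimationError):
            wald_ratio(h)


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self):
        h = make_instruments([0.5], [0.1], [0.05], [0.02])
        est = ivw(h, re_mode="multiplicative_random")
        wald = wald_ratio(h[0])
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_two_equal_weight_ratios_average(self):
        # Equal beta_exp and equal se_out: WLS through the origin averages ratios.
        h = make_instruments([0.5, 0.5], [0.1, 0.2], [0.05, 0.05], [0.02, 0.02])
        assert ivw(h, re_mode="fixed").beta == pytest.approx(0.3)

    def test_matches_statsmodels_wls_through_origin(self, rng):
        bx = rng.normal(0.1, 0.03, 20)
        by = 0.4 * bx + rng.normal(0, 0.01, 20)
        sy = rng.uniform(0.01, 0.03, 20)
        h = make_instruments(bx, by, sy=sy)
        est = ivw(h, re_mode="fixed")
        fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_mre_se_never_below_fixed_se(self, rng):
        bx = rng.normal(0.1, 0.03, 15)
        by = 0.4 * bx + rng.normal(0, 0.05, 15)  # overdispersed
        h = make_instruments(bx, by, sy=np.full(15, 0.01))
        assert ivw(h, re_mode="multiplicative_random").se >= ivw(h, re_mode="fixed").se

    def test_empty_set_rejected(self):
        with pytest.raises(EstimationError):
            ivw([])


class TestMREgger:
    def test_exact_proportional_fixture_recovers_slope_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_instruments(bx, 0.5 * bx)
        slope, intercept = mr_egger(h)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fixture_recovers_both_coefficients(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        h = make_instruments(bx, 0.05 + 0.5 * bx)
        slope, intercept = mr_egger(h)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta == pytest.approx(0.05, abs=1e-12)

    def test_orientation_to_positive_exposure_effects(self):
        # A negative-gamma instrument on the same affine law, after orientation.
        bx = np.array([0.1, -0.2, 0.3, 0.4])
        by = 0.05 + 0.5 * np.abs(bx)
        by[1] *= -1  # outcome effect flips with the exposure effect
        h = make_instruments(bx, by)
        slope, intercept = mr_egger(h)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta == pytest.approx(0.05, abs=1e-12)

    def test_matches_statsmodels_wls_with_intercept(self, rng):
        bx = np.abs(rng.normal(0.1, 0.03, 25))
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.01, 25)
        sy = rng.uniform(0.01, 0.03, 25)
        h = make_instruments(bx, by, sy=sy)
        slope, intercept = mr_egger(h)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert intercept.beta == pytest.approx(fit.params[0], rel=1e-9)
        assert slope.beta == pytest.approx(fit.params[1], rel=1e-9)

    def test_requires_three_instruments(self):
        with pytest.raises(EstimationError, match="3"):
            mr_egger(make_instruments([0.1, 0.2], [0.05, 0.1]))


def _median_oracle(ratios, weights):
    """Independently coded weighted-CDF interpolation at probability 0.5."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    total = w.sum()
    cum = 0.0
    s = []
    for wi in w:
        cum += wi
        s.append((cum - wi / 2) / total)
    for j in range(1, len(r)):
        if s[j] >= 0.5:
            frac = (0.5 - s[j - 1]) / (s[j] - s[j - 1])
            return r[j - 1] + frac * (r[j] - r[j - 1])
    return r[-1]


class TestWeightedMedian:
    def test_equal_weights_give_plain_median(self):
        h = make_instruments([1, 1, 1], [0.1, 0.2, 0.9], sy=[0.02, 0.02, 0.02])
        est = weighted_median(h, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_dominant_weight_pins_the_estimate(self):
        # One SNP carries ~99.9% of total weight via a tiny outcome SE.
        h = make_instruments(
            [1, 1, 1], [0.1, 0.5, 0.9], sy=[0.001, 1.0, 1.0]
        )
        est = weighted_median(h, n_boot=100, seed=1)
        assert round(est.beta, 3) == 0.1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_cdf_interpolation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 6)
        bx = rng.uniform(0.05, 0.3, n)
        by = rng.normal(0, 0.1, n)
        sy = rng.uniform(0.01, 0.1, n)
        h = make_instruments(bx, by, sy=sy)
        est = weighted_median(h, n_boot=10, seed=0)
        ratios = by / bx
        weights = bx**2 / sy**2
        assert est.beta == pytest.approx(_median_oracle(ratios, weights), rel=1e-12)

    def test_bootstrap_se_reproducible_under_seed(self):
        h = make_instruments([0.1, 0.2, 0.3, 0.4], [0.04, 0.09, 0.11, 0.17])
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        c = weighted_median(h, n_boot=200, seed=43)
        assert a.se == b.se
        assert a.se != c.se


def _kde_mode_oracle(ratios, weights, h):
    """Independently coded grid-argmax of the weighted Gaussian KDE."""
    grid = np.linspace(min(ratios) - 3 * h, max(ratios) + 3 * h, MODE_GRID_POINTS)
    best, best_d = grid[0], -1.0
    for g in grid:
        d = sum(w * np.exp(-0.5 * ((g - r) / h) ** 2) for r, w in zip(ratios, weights))
        if d > best_d:
            best, best_d = g, d
    return best


class TestMode:
    def test_identical_ratios_returned_for_any_phi(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_instruments(bx, 0.3 * bx)
        for phi in (0.25, 1.0, 4.0):
            assert mode_estimate(h, "simple", phi=phi, n_boot=50, seed=0).beta == 0.3

    def test_larger_cluster_wins(self):
        ratios = np.array([0.2] * 7 + [0.8] * 3) + np.linspace(-0.01, 0.01, 10)
        h = make_instruments(np.ones(10), ratios, sy=np.full(10, 0.02))
        est = mode_estimate(h, "simple", phi=1.0, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2, abs=0.05)

    def test_matches_kde_argmax_oracle(self, rng):
        bx = rng.uniform(0.05, 0.3, 8)
        by = rng.normal(0.05, 0.05, 8)
        sy = rng.uniform(0.01, 0.05, 8)
        h = make_instruments(bx, by, sy=sy)
        est = mode_estimate(h, "weighted", phi=1.0, n_boot=10, seed=0)
        ratios = by / bx
        w = (bx**2 / sy**2)
        w = w / w.sum()
        hband = mode_bandwidth(ratios, 1.0)
        assert est.beta == pytest.approx(_kde_mode_oracle(ratios, w, hband), rel=1e-12)

    def test_phi_scales_bandwidth_linearly(self, rng):
        ratios = rng.normal(0.3, 0.1, 12)
        assert mode_bandwidth(ratios, 2.0) == pytest.approx(2 * mode_bandwidth(ratios, 1.0))


class TestMVMR:
    def test_exact_two_exposure_system(self, rng):
        x = rng.normal(0.1, 0.05, 5)
        m = rng.normal(0.0, 0.08, 5)
        y = 0.4 * x + 0.1 * m
        ests = mvmr_ivw(np.column_stack([x, m]), y, np.full(5, 0.01))
        assert ests[0].beta == pytest.approx(0.4, abs=1e-10)
        assert ests[1].beta == pytest.approx(0.1, abs=1e-10)

    def test_orthogonal_null_mediator_leaves_exposure_coefficient_univariable(self):
        x = np.array([1.0, 1.0, -1.0, -1.0, 0.5, -0.5])
        m = np.array([1.0, -1.0, 1.0, -1.0, 0.0, 0.0])  # orthogonal to x
        y = 0.3 * x  # mediator truly null
        sy = np.full(6, 0.02)
        ests = mvmr_ivw(np.column_stack([x, m]), y, sy)
        h = make_instruments(x, y, sy=sy)
        assert ests[0].beta == pytest.approx(ivw(h, "fixed").beta, abs=1e-12)
        assert ests[1].beta == pytest.approx(0.0, abs=1e-12)

    def test_rank_and_collinearity_errors(self):
        with pytest.raises(EstimationError):
            mvmr_ivw(np.ones((2, 2)), np.ones(2), np.ones(2))
        x = np.linspace(0.1, 0.5, 6)
        with pytest.raises(CollinearityError):
            mvmr_ivw(np.column_stack([x, 2 * x]), 0.3 * x, np.full(6, 0.02))


class TestEstimatorProperties:
    def _flip(self, instruments, i):
        h = instruments[i]
        flipped = type(h)(
            snp_id=h.snp_id, beta_exp=-h.beta_exp, se_exp=h.se_exp,
            beta_out=-h.beta_out, se_out=h.se_out,
        )
        return instruments[:i] + [flipped] + instruments[i + 1 :]

    @pytest.mark.parametrize("i", [0, 2])
    def test_equivariance_under_allele_reorientation(self, rng, i):
        """Jointly flipping (beta_exp, beta_out) of any instrument changes nothing."""
        bx = rng.uniform(0.05, 0.3, 6)
        by = 0.4 * bx + rng.normal(0, 0.01, 6)
        h = make_instruments(bx, by)
        hf = self._flip(h, i)
        assert ivw(h).beta == pytest.approx(ivw(hf).beta, rel=1e-12)
        s1, i1 = mr_egger(h)
        s2, i2 = mr_egger(hf)
        assert s1.beta == pytest.approx(s2.beta, rel=1e-12)
        assert i1.beta == pytest.approx(i2.beta, rel=1e-12)
        wm1 = weighted_median(h, n_boot=10, seed=0)
        wm2 = weighted_median(hf, n_boot=10, seed=0)
        assert wm1.beta == pytest.approx(wm2.beta, rel=1e-12)

    def test_homogeneous_instruments_all_estimators_agree(self):
        bx = np.array([0.1, 0.15, 0.2, 0.3, 0.45])
        h = make_instruments(bx, 0.25 * bx)
        vals = [
            ivw(h).beta,
            mr_egger(h)[0].beta,
            weighted_median(h, n_boot=50, seed=0).beta,
            mode_estimate(h, "simple", n_boot=50, seed=0).beta,
            mode_estimate(h, "weighted", n_boot=50, seed=0).beta,
        ]
        assert np.allclose(vals, 0.25, atol=1e-6)

    def test_ci_brackets_the_estimate(self):
        h = make_instruments([0.1, 0.2, 0.3], [0.05, 0.08, 0.14])
        est = ivw(h)
        assert est.ci_low <= est.beta <= est.ci_high
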