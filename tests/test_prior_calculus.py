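"""Oracular hard-prior calculus: calibration, slopes, contour grids."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from priorpower.power_model import TestDesign, critical_r2
from priorpower.prior_calculus import (
    PriorSpec,
    contour_slope,
    critical_r2_grid,
    equivalent_strength_exact,
    inflated_threshold,
    population_ratio_approx,
    slope_scale,
)
from priorpower.stats_core import upper_quantile, upper_tail


def brute_force_equivalent_strength(fold, design, power, n=1e5):
    """Independent oracle: match critical R^2 of (fold*n, S=1) by solving in S."""
    target = critical_r2(fold * n, design, prior_strength=1.0, power=power)
    f = lambda ln_s: critical_r2(n, design, prior_strength=math.exp(ln_s),
                                 power=power) - target
    # bracket kept inside the monotone region z_I(S) > z_II
    return math.exp(optimize.brentq(f, 0.0, math.log(1e6), xtol=1e-13))


class TestInflatedThreshold:
    def test_hundredfold_prior(self, gwas):
        assert inflated_threshold(gwas, 100) == pytest.approx(5e-6, rel=1e-12)

    def test_identity_and_thousandfold(self, gwas):
        assert inflated_threshold(gwas, 1) == pytest.approx(5e-8, rel=1e-12)
        assert inflated_threshold(gwas, 1000) == pytest.approx(5e-5, rel=1e-12)

    def test_rejects_exhausted_burden(self, gwas):
        with pytest.raises(ValueError):
            inflated_threshold(gwas, 1e9)


class TestEquivalentStrength:
    def test_identity_fold(self, gwas):
        assert equivalent_strength_exact(1.0, gwas) == pytest.approx(1.0, rel=1e-10)

    @pytest.mark.parametrize("fold", [1.2, 1.4, 2.0])
    def test_matches_brute_force_contour_solve(self, gwas, fold):
        s = equivalent_strength_exact(fold, gwas, power=0.8)
        oracle = brute_force_equivalent_strength(fold, gwas, 0.8)
        assert s == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("fold, published", [(1.2, 16.8), (1.4, 124.2),
                                                 (2.0, 4321.5)])
    def test_near_published_calibration(self, gwas, fold, published):
        # exact solutions land within 1% of the published rounded values
        s = equivalent_strength_exact(fold, gwas, power=0.8)
        assert s == pytest.approx(published, rel=0.01)

    def test_independent_of_absolute_n(self, gwas):
        for fold in (1.3, 2.0):
            oracles = [brute_force_equivalent_strength(fold, gwas, 0.8, n=n)
                       for n in (1e3, 1e5, 1e7)]
            assert max(oracles) == pytest.approx(min(oracles), rel=1e-6)

    def test_composition_of_folds(self, gwas):
        # matching fold a then fold b equals matching fold a*b (ln S additive route)
        a, b = 1.2, 1.5
        z_ii = upper_quantile(0.8)
        z1 = gwas.significance_quantile()
        z_a = z_ii + (z1 - z_ii) / math.sqrt(a)
        # second step starts from the already-relaxed quantile z_a
        z_ab = z_ii + (z_a - z_ii) / math.sqrt(b)
        s_two_step = upper_tail(z_ab) / gwas.threshold
        s_direct = equivalent_strength_exact(a * b, gwas)
        assert math.log(s_two_step) == pytest.approx(math.log(s_direct), rel=1e-6)

    def test_rejects_fold_below_one(self, gwas):
        with pytest.raises(ValueError):
            equivalent_strength_exact(0.9, gwas)

    def test_rejects_unreachable_fold(self, gwas_halved):
        # as the fold grows, z_I(S) approaches z_II and the implied
        # two-sided threshold exceeds 1: no prior strength can match
        with pytest.raises(ValueError):
            equivalent_strength_exact(1e9, gwas_halved)


class TestPopulationRatioApprox:
    def test_thousandfold_prior_is_forty_percent(self, gwas_halved):
        # S = 1000 matched by ~40% more cohort under the printed zeta = 5.45
        ratio = population_ratio_approx(1.0, 1000.0, gwas_halved, method="linear")
        assert ratio == pytest.approx(1.40, abs=0.005)

    @pytest.mark.parametrize("method", ["linear", "exponential"])
    def test_equal_strengths_give_unity(self, gwas, method):
        assert population_ratio_approx(7.0, 7.0, gwas, method=method) == 1.0

    def test_linear_vs_exponential_second_order(self, gwas_halved):
        scale = slope_scale(gwas_halved, 0.8)
        for ratio in (2.0, 10.0):
            eps = math.log(ratio) / scale
            lin = population_ratio_approx(1.0, ratio, gwas_halved, method="linear")
            expo = population_ratio_approx(1.0, ratio, gwas_halved, method="exponential")
            assert abs(lin - expo) <= eps**2

    def test_linear_underestimates_exact_fold(self, gwas):
        # for a large strength step the log-linear form undershoots the
        # true population fold recovered by inverting the exact calibration
        s2 = 1000.0
        approx_fold = population_ratio_approx(1.0, s2, gwas, method="linear")
        f = lambda fold: equivalent_strength_exact(fold, gwas) - s2
        exact_fold = optimize.brentq(f, 1.0 + 1e-9, 10.0)
        assert approx_fold < exact_fold


class TestSlopeScale:
    def test_printed_gwas_value(self, gwas_halved):
        assert slope_scale(gwas_halved, 0.8) == pytest.approx(17.15, abs=0.005)

    def test_half_power_reduces_to_half_zeta_squared(self, gwas):
        zeta = gwas.significance_quantile()
        assert slope_scale(gwas, 0.5) == pytest.approx(zeta**2 / 2, rel=1e-12)

    def test_monotone_in_power(self, gwas):
        vals = [slope_scale(gwas, p) for p in (0.5, 0.8, 0.9, 0.99)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestContourSlope:
    def test_local_slope_at_no_prior(self, gwas):
        assert contour_slope(gwas, 0.8, mode="local_at", s_from=1.0) == pytest.approx(
            17.0, abs=0.05)

    def test_secant_to_strength_100(self, gwas):
        s = contour_slope(gwas, 0.8, mode="secant", s_from=1.0, s_to=100.0)
        assert s == pytest.approx(14.4, abs=0.05)

    def test_local_slope_matches_mills_ratio_oracle(self, gwas):
        # d ln S/d ln N at S=1 is (phi(zeta)/Sc(zeta)) * (zeta - z_II) / 2
        zeta = gwas.significance_quantile()
        z_ii = upper_quantile(0.8)
        oracle = (stats.norm.pdf(zeta) / stats.norm.sf(zeta)) * (zeta - z_ii) / 2
        slope = contour_slope(gwas, 0.8, mode="local_at", s_from=1.0, rel_step=0.001)
        assert slope == pytest.approx(oracle, rel=1e-3)

    def test_degenerate_secant_rejected(self, gwas):
        with pytest.raises(ValueError):
            contour_slope(gwas, mode="secant", s_from=10.0, s_to=10.0)


class TestCriticalR2Grid:
    def test_monotone_in_both_axes(self, gwas):
        grid = critical_r2_grid(np.geomspace(1e3, 1e7, 20),
                                np.geomspace(1, 1e3, 20), gwas)
        vals = grid.to_numpy()
        assert (np.diff(vals, axis=1) < 0).all()   # decreasing in N
        assert (np.diff(vals, axis=0) < 0).all()   # decreasing in S

    def test_no_prior_row_matches_power_model(self, gwas):
        n_vals = np.geomspace(1e3, 1e7, 5)
        grid = critical_r2_grid(n_vals, [1.0], gwas)
        for n in n_vals:
            assert grid.loc[1.0, n] == pytest.approx(critical_r2(n, gwas), rel=1e-12)

    def test_contour_matches_power_law_form(self, gwas):
        # N(S) at fixed critical R^2 tracks S^(-2/(zeta (zeta - z_II))) within 5%
        from priorpower.power_model import required_n

        zeta = gwas.significance_quantile()
        z_ii = upper_quantile(0.8)
        r2 = 1e-4
        approx_const = (zeta - z_ii) ** 2 * (1 - r2) / r2
        for s in (1.0, 3.0, 10.0, 30.0, 100.0):
            exact = required_n(r2, gwas, prior_strength=s)
            approx = s ** (-2 / (zeta * (zeta - z_ii))) * approx_const
            assert approx == pytest.approx(exact, rel=0.05)


class TestPriorSpec:
    def test_validation(self):
        PriorSpec(strength=10, accuracy=0.9)
        with pytest.raises(ValueError):
            PriorSpec(strength=0.5)
        with pytest.raises(ValueError):
            PriorSpec(strength=2, accuracy=0.0)
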