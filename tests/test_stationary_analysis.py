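import math

import numpy as np
import pytest

from rdhill import (
    ToyParams,
    deterministic_mean_P,
    empty_bin_prob,
    hybrid_mean_P_exact,
    jensen_gap,
    loglog_slope,
    mean_P_exact,
    mean_syn_propensity_exact,
    total_E_pmf,
    toy_params,
    validity_threshold,
)


def _poisson_pmf_independent(n: int, lam: float) -> float:
    """Independent oracle: Poisson pmf via log-factorial accumulation."""
    if lam == 0:
        return 1.0 if n == 0 else 0.0
    log_p = -lam + n * math.log(lam) - math.lgamma(n + 1)
    return math.exp(log_p)


def _mean_hill_brute(lam: float, thr: float, nh: float, scale: float) -> float:
    """Independent oracle: scale * E[hill(n; thr)] under n ~ Poisson(lam)."""
    total = 0.0
    for n in range(1, int(lam + 30 * math.sqrt(lam + 1) + 60)):
        total += _poisson_pmf_independent(n, lam) * n**nh / (thr**nh + n**nh)
    return scale * total


class TestTotalEnzymeLaw:
    def test_pmf_at_zero(self, params25):
        assert total_E_pmf(params25, 0) == pytest.approx(math.exp(-25.0))

    def test_mean_and_variance_from_pmf(self, params25):
        n = np.arange(0, 200)
        p = total_E_pmf(params25, n)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        mean = (n * p).sum()
        var = ((n - mean) ** 2 * p).sum()
        assert mean == pytest.approx(25.0, abs=1e-9)
        assert var == pytest.approx(mean, abs=1e-6)


class TestEmptyBinProbability:
    def test_closed_form(self, params25):
        assert empty_bin_prob(params25, 100) == pytest.approx(math.exp(-0.25))

    def test_whole_domain_window_matches_total_pmf(self, params25):
        assert empty_bin_prob(params25, 50, m=50) == pytest.approx(
            float(total_E_pmf(params25, 0)))

    def test_binomial_thinning_series_converges_to_closed_form(self, params25):
        # independent oracle: the direct thinning series
        K = 100
        alpha = params25.alpha
        N = int(alpha + 20 * math.sqrt(alpha))
        series = sum(_poisson_pmf_independent(n, alpha) * (1 - 1 / K) ** n
                     for n in range(N + 1))
        assert series == pytest.approx(empty_bin_prob(params25, K), abs=1e-10)


class TestMeanSynthesisPropensity:
    def test_bracket_in_the_switch_regime(self, params25):
        # K = 128: K_m*h < 0.5 and alpha/K < 1/3, so the mean propensity
        # sits between 0.94 and 1.00 times k_syn*h*(1 - P(empty))
        K = 128
        h = 1.0 / K
        occ = 1.0 - empty_bin_prob(params25, K)
        got = mean_syn_propensity_exact(params25, K)
        assert 0.94 * params25.k_syn * h * occ <= got <= params25.k_syn * h * occ

    def test_fine_grid_linearization(self, params25):
        # mean propensity approaches k_syn*h*alpha/K as the grid refines
        K = 10**5
        h = 1.0 / K
        linear = params25.k_syn * h * params25.alpha / K
        assert mean_syn_propensity_exact(params25, K) == pytest.approx(
            linear, rel=2e-4)

    def test_no_enzyme_no_synthesis(self):
        p = toy_params(K_m=25.0, k_s=0.0)
        assert mean_syn_propensity_exact(p, 10) == 0.0


class TestMeanProduct:
    def test_well_mixed_against_independent_series(self, params25):
        expected = _mean_hill_brute(25.0, 25.0, 4.0, 100.0)
        assert mean_P_exact(params25, 1) == pytest.approx(expected, rel=1e-9)

    def test_whole_domain_window_equals_well_mixed(self, params25):
        assert mean_P_exact(params25, 50, m=50) == pytest.approx(
            mean_P_exact(params25, 1), rel=1e-12)

    def test_fine_grid_linear_law(self, params25):
        # K=1000: the linear law (k_syn/k_deg)*alpha*h = 2.5
        linear = params25.k_syn / params25.k_deg * params25.alpha / 1000
        assert mean_P_exact(params25, 1000) == pytest.approx(linear, rel=0.05)

    def test_fixed_window_breaks_at_small_h(self, params25):
        """Fixed m=5 smoothing: decaying toward zero once K is far above
        the no-smoothing validity threshold scaled by m."""
        ks = [400, 800, 1600, 3200, 6400]
        vals = [mean_P_exact(params25, K, m=5) for K in ks]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        # and it does collapse: an order of magnitude over this range
        assert vals[-1] < vals[0] / 3


class TestHybridSlowScale:
    def test_matches_independent_series(self, params50):
        expected = _mean_hill_brute(25.0, 50.0, 4.0, 100.0)
        got = hybrid_mean_P_exact(params50)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(6.9582, abs=2e-4)

    def test_large_threshold_suppresses_synthesis(self):
        assert hybrid_mean_P_exact(toy_params(K_m=1e6)) < 1e-15

    def test_exceeds_deterministic_value_below_threshold(self, params50):
        # Jensen: f convex where the enzyme level sits below K_m*L
        assert hybrid_mean_P_exact(params50) > deterministic_mean_P(params50)


class TestJensenGap:
    def test_direction_for_subthreshold_enzyme(self, params50):
        averaged, of_average = jensen_gap(params50)
        assert averaged > of_average

    def test_midpoint_value_at_matched_threshold(self, params25):
        _, of_average = jensen_gap(params25)
        assert of_average == pytest.approx(0.5 * params25.k_syn * params25.L)

    def test_consistency_with_slow_scale_mean(self, params50):
        averaged, _ = jensen_gap(params50)
        assert averaged == pytest.approx(
            hybrid_mean_P_exact(params50) * params50.k_deg, rel=1e-12)


class TestValidityThreshold:
    @pytest.mark.parametrize("km,expect", [(25.0, 75.0), (50.0, 100.0)])
    def test_printed_values(self, km, expect):
        assert validity_threshold(toy_params(K_m=km)) == expect

    def test_degenerate_limit(self):
        p = toy_params(K_m=1e-9, k_s=1e-9)
        assert validity_threshold(p) < 1e-6


class TestLogLogSlope:
    def test_exact_linear_scaling(self):
        h = np.array([0.1, 0.01, 0.001])
        assert loglog_slope(h, 7.0 * h) == pytest.approx(1.0, abs=1e-12)

    def test_exact_quadratic_scaling(self):
        h = np.geomspace(1e-3, 1e-1, 5)
        assert loglog_slope(h, 3.0 * h**2) == pytest.approx(2.0, abs=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            loglog_slope(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            loglog_slope(np.array([0.1, -0.2, 0.3]), np.array([1.0, 2.0, 3.0]))


class TestDeterministicMeanP:
    def test_matched_threshold_gives_midpoint(self, params25):
        assert deterministic_mean_P(params25) == pytest.approx(50.0)

    def test_subthreshold_enzyme(self, params50):
        assert deterministic_mean_P(params50) == pytest.approx(100.0 / 17.0)

    def test_no_synthesis(self):
        assert deterministic_mean_P(toy_params(K_m=25.0, k_syn=0.0)) == 0.0


class TestToyParamsValidation:
    def test_alpha_derivation(self):
        p = ToyParams(k_s=3.0, k_d=0.5, L=2.0)
        assert p.alpha == pytest.approx(12.0)

    def test_rejects_nonpositive_constants(self):
        with pytest.raises(ValueError):
            ToyParams(K_m=0.0)
        with pytest.raises(ValueError):
            ToyParams(k_d=-1.0)
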