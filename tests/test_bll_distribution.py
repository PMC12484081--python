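"""Exposure-distribution representation and summary-statistic fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import ndtr

from leadiq import (
    distribution_mean,
    exceedance,
    fit_lognormal_mean_exceedance,
    fit_lognormal_two_exceedances,
    make_degenerate,
    make_lognormal,
    make_normal,
)
from leadiq.errors import FeasibilityError

MU, SIGMA = 1.2, 0.6
REF = make_lognormal(MU, SIGMA)
REF_MEAN = math.exp(MU + SIGMA**2 / 2)  # = exp(1.38) ~ 3.9749
REF_P5 = float(stats.lognorm.sf(5.0, SIGMA, scale=math.exp(MU)))  # ~ 0.2474


class TestExceedance:
    def test_point_mass_below_threshold(self):
        assert exceedance(make_degenerate(4.0), 5.0) == 0.0

    def test_point_mass_above_threshold(self):
        assert exceedance(make_degenerate(4.0), 3.0) == 1.0

    def test_lognormal_matches_scipy_survival(self):
        # independent route: scipy's lognormal survival function
        assert exceedance(REF, 5.0) == pytest.approx(REF_P5, abs=1e-12)
        assert exceedance(REF, 5.0) == pytest.approx(0.2474, abs=1e-4)

    def test_lognormal_matches_monte_carlo(self):
        rng = np.random.default_rng(42)
        draws = np.exp(MU + SIGMA * rng.standard_normal(10**6))
        mc = (draws > 5.0).mean()
        se = math.sqrt(mc * (1 - mc) / 10**6)
        assert abs(exceedance(REF, 5.0) - mc) < 4 * se

    def test_monotone_in_threshold(self):
        vals = [exceedance(REF, t) for t in (1.0, 2.0, 5.0, 10.0, 20.0)]
        assert vals == sorted(vals, reverse=True)

    def test_normal_is_truncated_and_renormalized(self):
        d = make_normal(1.0, 2.0)
        expected = ndtr((1.0 - 3.0) / 2.0) / ndtr(0.5)
        assert exceedance(d, 3.0) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            exceedance(REF, 0.0)


class TestDistributionMean:
    @pytest.mark.parametrize(
        "dist, expected",
        [
            (make_degenerate(7.5), 7.5),
            (REF, REF_MEAN),
            (make_normal(6.0, 1.0), 6.0),
        ],
    )
    def test_analytic_means(self, dist, expected):
        assert distribution_mean(dist) == pytest.approx(expected, rel=1e-12)

    def test_lognormal_mean_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        draws = np.exp(MU + SIGMA * rng.standard_normal(10**6))
        se = draws.std() / 1000.0
        assert abs(distribution_mean(REF) - draws.mean()) < 4 * se


class TestFitMeanExceedance:
    def test_smaller_sigma_root(self):
        d = fit_lognormal_mean_exceedance(REF_MEAN, REF_P5, 5.0, "smaller_sigma")
        assert d.params[0] == pytest.approx(1.2, abs=1e-9)
        assert d.params[1] == pytest.approx(0.6, abs=1e-9)

    def test_larger_sigma_root(self):
        d = fit_lognormal_mean_exceedance(REF_MEAN, REF_P5, 5.0, "larger_sigma")
        assert d.params[1] == pytest.approx(0.764793, abs=1e-5)
        assert d.params[0] == pytest.approx(1.087546, abs=1e-5)

    @pytest.mark.parametrize("policy", ["smaller_sigma", "larger_sigma"])
    def test_both_roots_satisfy_constraints(self, policy):
        d = fit_lognormal_mean_exceedance(REF_MEAN, REF_P5, 5.0, policy)
        assert distribution_mean(d) == pytest.approx(REF_MEAN, rel=1e-10)
        assert exceedance(d, 5.0) == pytest.approx(REF_P5, abs=1e-10)

    def test_match_second_exceedance_selects_true_root(self):
        p10 = exceedance(REF, 10.0)
        d = fit_lognormal_mean_exceedance(
            REF_MEAN, REF_P5, 5.0, "match_second_exceedance",
            second_p=p10, second_threshold=10.0,
        )
        assert d.params[1] == pytest.approx(SIGMA, abs=1e-9)

    def test_infeasible_reports_admissible_range(self):
        with pytest.raises(FeasibilityError, match="admissible p range"):
            fit_lognormal_mean_exceedance(5.0, 0.9, 5.0)

    def test_feasibility_edge_returns_sigma_equal_z(self):
        mean, t = REF_MEAN, 5.0
        z_edge = math.sqrt(2 * math.log(t / mean))
        p_edge = float(ndtr(-z_edge))
        d = fit_lognormal_mean_exceedance(mean, p_edge, t)
        assert d.params[1] == pytest.approx(z_edge, abs=1e-6)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_boundary_p_rejected(self, p):
        with pytest.raises(ValueError):
            fit_lognormal_mean_exceedance(REF_MEAN, p, 5.0)

    def test_sigma_monotone_in_p_for_fixed_mean(self):
        mean, t = REF_MEAN, 5.0
        p_max = float(ndtr(-math.sqrt(2 * math.log(t / mean))))
        ps = np.linspace(0.01, 0.999 * p_max, 20)
        sigmas = [
            fit_lognormal_mean_exceedance(mean, p, t).params[1] for p in ps
        ]
        assert all(a < b for a, b in zip(sigmas, sigmas[1:]))


class TestFitTwoExceedances:
    def test_recovers_reference_params(self):
        p10 = exceedance(REF, 10.0)
        d = fit_lognormal_two_exceedances(REF_P5, p10)
        assert d.params[0] == pytest.approx(MU, abs=1e-9)
        assert d.params[1] == pytest.approx(SIGMA, abs=1e-9)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError, match="decrease"):
            fit_lognormal_two_exceedances(0.5, 0.5)

    @pytest.mark.parametrize("p5, p10", [(0.0, 0.0), (1.0, 0.5), (0.5, 1.0)])
    def test_boundary_values_rejected(self, p5, p10):
        with pytest.raises(ValueError):
            fit_lognormal_two_exceedances(p5, p10)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    mu=st.floats(-1.0, 3.0),
    sigma=st.floats(0.05, 1.5),
)
def test_forward_inverse_round_trip(mu, sigma):
    """Closed-form summaries of any lognormal are inverted back exactly."""
    d = make_lognormal(mu, sigma)
    p5, p10 = exceedance(d, 5.0), exceedance(d, 10.0)
    if not (1e-7 < p10 < p5 < 1 - 1e-7):
        return  # tail too extreme for double precision to invert to 1e-8
    d2 = fit_lognormal_two_exceedances(p5, p10)
    assert d2.params[0] == pytest.approx(mu, abs=1e-8)
    assert d2.params[1] == pytest.approx(sigma, abs=1e-8)
    d3 = fit_lognormal_mean_exceedance(
        distribution_mean(d), p5, 5.0, "match_second_exceedance",
        second_p=p10, second_threshold=10.0,
    )
    assert d3.params[0] == pytest.approx(mu, abs=1e-8)
    assert d3.params[1] == pytest.approx(sigma, abs=1e-8)


def test_degenerate_family_rules():
    assert make_degenerate(3.5).params == (3.5,)
    assert make_degenerate(0.0).params == (0.0,)
    with pytest.raises(ValueError):
        make_degenerate(-1.0)
    for m, t in [(2.0, 5.0), (8.0, 5.0)]:
        assert exceedance(make_degenerate(m), t) == (1.0 if m > t else 0.0)
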