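"""Closed-form age and transit-time machinery for autonomous systems."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctransit import (
    CompartmentalError,
    CompartmentalSystem,
    RandomSystemSpec,
    default_age_grid,
    mean_system_age_equilibrium,
    pool_age_density,
    random_system,
    steady_state,
    system_age_pdf,
    transit_time_pdf,
    tt_moments,
    tt_quantile,
    validate_compartmental,
)

TAIL_TOL = 1e-4


class TestValidation:
    def test_one_pool_decay_is_valid(self):
        assert validate_compartmental([[-1.0]]).ok

    def test_positive_diagonal_rejected(self):
        rep = validate_compartmental([[1.0]])
        assert not rep.ok
        assert any("diagonal" in p for p in rep.problems)

    def test_negative_offdiagonal_rejected(self):
        assert not validate_compartmental([[-1.0, -0.1], [0.0, -1.0]]).ok

    def test_column_sum_violation_rejected(self):
        # transfers out of pool 1 exceed its total loss rate
        assert not validate_compartmental([[-1.0, 0.0], [2.0, -1.0]]).ok

    def test_non_square_raises(self):
        with pytest.raises(CompartmentalError):
            validate_compartmental(np.zeros((2, 3)))

    def test_emanuel_release_rates_nonnegative(self, emanuel):
        rep = validate_compartmental(emanuel.B, require_invertible=True)
        assert rep.ok
        assert np.all(rep.release_rates >= 0)
        # total release balances total input at steady state
        assert rep.release_rates @ steady_state(emanuel).x_star == pytest.approx(113.0)

    def test_constructor_rejects_bad_inputs(self):
        with pytest.raises(CompartmentalError):
            CompartmentalSystem(B=[[-1.0]], u=[-1.0])
        with pytest.raises(CompartmentalError):
            CompartmentalSystem(B=[[-1.0]], u=[0.0])
        with pytest.raises(CompartmentalError):
            CompartmentalSystem(B=[[1.0]], u=[1.0])


class TestSteadyState:
    def test_one_pool(self):
        ss = steady_state(CompartmentalSystem(B=[[-0.25]], u=[1.0]))
        assert ss.x_star == pytest.approx([4.0])

    def test_five_pool_stocks_by_flux_balance(self, emanuel):
        # every pool's input flux equals its loss rate times the stock,
        # e.g. detritus receives 21 + 15 + 12 = 48 PgC/yr and cycles at 48/81 /yr
        ss = steady_state(emanuel)
        np.testing.assert_allclose(ss.x_star, [37.0, 452.0, 69.0, 81.0, 1121.0], rtol=1e-12)
        assert ss.total_stock == pytest.approx(1760.0)
        assert ss.total_input == pytest.approx(113.0)

    def test_singular_matrix_raises(self):
        # closed two-pool loop conserves mass: no steady state with input
        B = [[-1.0, 1.0], [1.0, -1.0]]
        with pytest.raises(CompartmentalError, match="singular"):
            steady_state(CompartmentalSystem(B=B, u=[1.0, 0.0]))


class TestAgeDensities:
    def test_one_pool_age_density_is_exponential(self, one_pool):
        ages = default_age_grid(one_pool)
        d = pool_age_density(one_pool, ages)
        np.testing.assert_allclose(d.values[:, 0], 0.5 * np.exp(-0.5 * ages), rtol=1e-9)

    def test_zero_stock_pool_rejected(self):
        sys = CompartmentalSystem(B=[[-1.0, 0.0], [0.0, -1.0]], u=[1.0, 0.0])
        with pytest.raises(CompartmentalError, match="zero stock"):
            pool_age_density(sys)

    def test_emanuel_per_pool_normalization(self, emanuel):
        d = pool_age_density(emanuel)
        ints = d.integral()
        # truncation loses at most the tail mass; quadrature adds O((h k)^2)
        assert np.all(ints > 1 - 2 * TAIL_TOL) and np.all(ints < 1 + 2 * TAIL_TOL)

    def test_slowest_pool_dominates_mean_age(self, emanuel):
        d = pool_age_density(emanuel)
        means = d.mean_age()
        assert means[4] > 10 * means[0]  # soil carbon far older than foliage

    def test_one_pool_system_age(self, one_pool):
        ages = default_age_grid(one_pool)
        d = system_age_pdf(one_pool, ages)
        np.testing.assert_allclose(d.values, 0.5 * np.exp(-0.5 * ages), rtol=1e-9)

    def test_system_age_mean_matches_closed_form(self, emanuel):
        d = system_age_pdf(emanuel)
        closed = mean_system_age_equilibrium(emanuel)
        # numeric grid mean carries trapezoid + truncation error only
        assert d.mean_age() == pytest.approx(closed, rel=1e-3)


class TestTransitTime:
    def test_one_pool_is_exponential(self, one_pool):
        ages = default_age_grid(one_pool)
        d = transit_time_pdf(one_pool, ages)
        np.testing.assert_allclose(d.values.sum(axis=1), 0.5 * np.exp(-0.5 * ages), rtol=1e-9)
        mean, sd = tt_moments(one_pool)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(2.0)
        assert tt_quantile(one_pool, 0.5) == pytest.approx(np.log(2) / 0.5, rel=1e-9)

    def test_decomposition_sums_to_total(self, emanuel):
        d = transit_time_pdf(emanuel)
        total = d.values.sum(axis=1)
        assert np.trapezoid(total, d.ages) == pytest.approx(1.0, abs=2 * TAIL_TOL)

    def test_mean_closed_form_vs_numeric_integral(self, emanuel):
        # two independent routes: 1^T(-B^-1)u/||u|| vs trapezoid of tau f_T
        mean, _ = tt_moments(emanuel)
        d = transit_time_pdf(emanuel, default_age_grid(emanuel, max_age=4000.0))
        numeric = np.trapezoid(d.values.sum(axis=1) * d.ages, d.ages)
        assert numeric == pytest.approx(mean, rel=1e-3)

    def test_mean_equals_stock_over_input(self, emanuel):
        mean, _ = tt_moments(emanuel)
        ss = steady_state(emanuel)
        assert mean == pytest.approx(ss.total_stock / ss.total_input, rel=1e-10)

    def test_quantiles_monotone_and_median_below_mean(self, emanuel):
        qs = [tt_quantile(emanuel, a) for a in (0.05, 0.25, 0.5, 0.75, 0.95)]
        assert np.all(np.diff(qs) > 0)
        mean, _ = tt_moments(emanuel)
        assert tt_quantile(emanuel, 0.5) < mean  # right-skewed phase-type

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.5])
    def test_quantile_rejects_bad_levels(self, emanuel, alpha):
        with pytest.raises(ValueError):
            tt_quantile(emanuel, alpha)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**20), n=st.integers(1, 4))
def test_random_system_densities_normalize(seed, n):
    """System-age and transit-time pdfs integrate to ~1 for any valid system."""
    sys = random_system(RandomSystemSpec(n=n, seed=seed))
    ss = steady_state(sys)
    ages = default_age_grid(sys)
    fa = system_age_pdf(sys, ages, ss)
    ft = transit_time_pdf(sys, ages)
    assert fa.integral() == pytest.approx(1.0, abs=2 * TAIL_TOL)
    assert np.trapezoid(ft.values.sum(axis=1), ages) == pytest.approx(1.0, abs=2 * TAIL_TOL)
    assert np.all(fa.values >= 0)
    assert np.all(ft.values >= 0)
    # exact steady-state identity, both closed forms
    mean, _ = tt_moments(sys)
    assert mean == pytest.approx(ss.total_stock / ss.total_input, rel=1e-10)
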