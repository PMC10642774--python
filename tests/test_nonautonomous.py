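"""Trajectories, state-transition operators and backward transit times."""

import numpy as np
import pytest
from scipy.linalg import expm

from ctransit import (
    CompartmentalSystem,
    GlobalChangeForcing,
    StateTransitionCache,
    TimeDependentSystem,
    age_mass_density,
    btt_distribution,
    btt_summary_series,
    default_age_grid,
    mean_system_age,
    mean_system_age_equilibrium,
    solve_trajectory,
    state_transition,
    steady_state,
    transit_time_pdf,
    tt_moments,
    tt_quantile,
)


@pytest.fixture
def constant_tds(emanuel):
    return TimeDependentSystem(base=emanuel, t0=1850.0)


@pytest.fixture(scope="module")
def combined_tds():
    return GlobalChangeForcing(co2_on=True, temp_on=True).to_tds()


class TestTrajectory:
    def test_equilibrium_is_fixed_point(self, constant_tds):
        t = np.linspace(1850.0, 1950.0, 11)
        y = solve_trajectory(constant_tds, t)
        np.testing.assert_allclose(y, np.tile(constant_tds.x0, (11, 1)), rtol=1e-6)

    def test_one_pool_step_input_relaxation(self):
        # input doubles at t0: x(t) = u2/k + (x0 - u2/k) e^{-kt}
        base = CompartmentalSystem(B=[[-0.5]], u=[1.0])
        tds = TimeDependentSystem(base=base, u_t=lambda t: np.array([2.0]))
        t = np.linspace(0.0, 20.0, 41)
        y = solve_trajectory(tds, t)[:, 0]
        expect = 4.0 + (2.0 - 4.0) * np.exp(-0.5 * t)
        np.testing.assert_allclose(y, expect, rtol=1e-6)

    def test_combined_run_net_uptake_and_mass_balance(self, combined_tds):
        t = np.arange(1850.0, 2020.5, 0.25)
        y = solve_trajectory(combined_tds, t)
        total = y.sum(axis=1)
        assert total[-1] > total[0]  # inputs grow faster than release
        gpp = np.array([combined_tds.u_t(tt).sum() for tt in t])
        re = np.array([combined_tds.release_rates(tt) @ y[k] for k, tt in enumerate(t)])
        lhs = total[-1] - total[0]
        rhs = np.trapezoid(gpp - re, t)
        assert lhs == pytest.approx(rhs, abs=1e-3)  # PgC over 170 yr

    def test_grid_before_t0_rejected(self, constant_tds):
        with pytest.raises(ValueError):
            solve_trajectory(constant_tds, [1840.0, 1860.0])


class TestStateTransition:
    def test_identity_at_equal_times(self, combined_tds):
        np.testing.assert_allclose(state_transition(combined_tds, 1900.0, 1900.0), np.eye(5))

    def test_autonomous_limit_is_matrix_exponential(self, constant_tds, emanuel):
        phi = state_transition(constant_tds, 1850.0, 1860.0)
        np.testing.assert_allclose(phi, expm(10.0 * emanuel.B), atol=1e-8)

    def test_backward_evaluation_rejected(self, combined_tds):
        with pytest.raises(ValueError):
            state_transition(combined_tds, 1900.0, 1850.0)

    def test_cocycle_on_combined_run(self, combined_tds):
        phi_02 = state_transition(combined_tds, 1850.0, 1950.0)
        phi_01 = state_transition(combined_tds, 1850.0, 1900.0)
        phi_12 = state_transition(combined_tds, 1900.0, 1950.0)
        assert np.abs(phi_02 - phi_12 @ phi_01).max() < 1e-6

    def test_cache_matches_direct_and_stays_substochastic(self, combined_tds):
        times = np.arange(1850.0, 1861.0)
        cache = StateTransitionCache(combined_tds, times)
        np.testing.assert_allclose(cache.phi(1850.0), np.eye(5))
        direct = state_transition(combined_tds, 1850.0, 1860.0)
        np.testing.assert_allclose(cache.phi(1860.0), direct, atol=1e-7)
        # off-grid evaluation solves from the nearest node
        mid = cache.phi(1855.5)
        np.testing.assert_allclose(mid, state_transition(combined_tds, 1850.0, 1855.5), atol=1e-7)
        for t in [1855.0, 1855.5, 1860.0]:
            phi = cache.phi(t)
            assert phi.min() > -1e-9
            assert phi.sum(axis=0).max() < 1 + 1e-9  # mass cannot be created


class TestAgeMassDensity:
    def test_equilibrium_age_structure_at_t0(self, constant_tds, emanuel):
        ages = default_age_grid(emanuel)
        m = age_mass_density(constant_tds, 1850.0, ages)
        expect = np.array([expm(a * emanuel.B) @ emanuel.u for a in ages[::50]])
        np.testing.assert_allclose(m.values[::50], expect, rtol=1e-8, atol=1e-12)

    def test_constant_forcing_time_invariant(self, constant_tds):
        ages = np.linspace(0.0, 60.0, 301)
        m1 = age_mass_density(constant_tds, 1855.0, ages)
        m2 = age_mass_density(constant_tds, 1905.0, ages)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-6)

    def test_combined_run_mass_conservation(self, combined_tds, emanuel):
        # componentwise integral of m(2020, a) matches the trajectory stocks
        ages = default_age_grid(emanuel, max_age=6000.0)
        m = age_mass_density(combined_tds, 2020.0, ages)
        stocks = solve_trajectory(combined_tds, [1850.0, 2020.0])[-1]
        np.testing.assert_allclose(m.integral(), stocks, rtol=1e-3)

    def test_before_t0_rejected(self, constant_tds):
        with pytest.raises(ValueError):
            age_mass_density(constant_tds, 1800.0)


class TestBTT:
    def test_autonomous_reduction_to_closed_form(self, constant_tds, emanuel):
        # with constant forcing the BTT density is the equilibrium phase-type
        # density at every evaluation time
        ages = default_age_grid(emanuel)
        ft = transit_time_pdf(emanuel, ages).values.sum(axis=1)
        for t in [1850.0, 1893.0, 1990.0]:
            d = btt_distribution(constant_tds, t, ages)
            assert np.abs(d.density / 113.0 - ft).max() < 1e-6

    def test_one_pool_time_varying_input(self):
        # r(t, a) = k u(t-a) e^{-ka} for ages younger than the run
        base = CompartmentalSystem(B=[[-0.5]], u=[1.0])
        u_t = lambda t: np.array([1.0 + 0.5 * np.sin(0.3 * t)])
        tds = TimeDependentSystem(base=base, u_t=u_t)
        ages = np.linspace(0.0, 30.0, 601)
        d = btt_distribution(tds, 40.0, ages)
        expect = 0.5 * np.array([u_t(40.0 - a)[0] for a in ages]) * np.exp(-0.5 * ages)
        np.testing.assert_allclose(d.density, expect, rtol=1e-6, atol=1e-10)

    def test_summary_series_constant_under_constant_forcing(self, constant_tds, emanuel):
        s = btt_summary_series(constant_tds, [1850.0, 1900.0, 1950.0])
        for col in ["gpp", "re", "mean_btt", "median_btt", "q95", "total_stock"]:
            assert s[col].std() == pytest.approx(0.0, abs=1e-5 * abs(s[col].mean()))
        mean, _ = tt_moments(emanuel)
        assert s["mean_btt"].iloc[0] == pytest.approx(mean, rel=1e-4)
        assert s["median_btt"].iloc[0] == pytest.approx(tt_quantile(emanuel, 0.5), rel=1e-4)
        assert s["q95"].iloc[0] == pytest.approx(tt_quantile(emanuel, 0.95), rel=1e-4)
        assert s["re"].iloc[0] == pytest.approx(113.0, rel=1e-6)

    def test_total_respiration_matches_release_of_stocks(self, combined_tds):
        d = btt_distribution(combined_tds, 1950.0)
        stocks = solve_trajectory(combined_tds, [1850.0, 1950.0])[-1]
        re = combined_tds.release_rates(1950.0) @ stocks
        assert d.total_respiration == pytest.approx(re, rel=1e-4)

    def test_quantile_validation(self, constant_tds):
        d = btt_distribution(constant_tds, 1860.0)
        with pytest.raises(ValueError):
            d.quantile(1.2)
        assert d.quantile(0.25) < d.median < d.quantile(0.95)


class TestMeanSystemAge:
    def test_one_pool_constant(self):
        base = CompartmentalSystem(B=[[-0.5]], u=[1.0])
        tds = TimeDependentSystem(base=base)
        assert mean_system_age(tds, 30.0) == pytest.approx(2.0, rel=1e-4)

    def test_equilibrium_route_equivalence(self, constant_tds, emanuel):
        closed = mean_system_age_equilibrium(emanuel)
        assert mean_system_age(constant_tds, 1850.0) == pytest.approx(closed, rel=1e-4)

    def test_emanuel_age_exceeds_transit_time(self, constant_tds, emanuel):
        mean_tt, _ = tt_moments(emanuel)
        assert mean_system_age(constant_tds, 1850.0) > mean_tt
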