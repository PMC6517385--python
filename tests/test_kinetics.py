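"""Kinetics: rates, closed form vs numerical integration, pulse descriptors."""

import itertools
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from colloidpulse.kinetics import (
    ConcentrationState,
    KineticParams,
    RnaTrajectory,
    closed_form_rna,
    ntp_mass_balance,
    ntp_rate,
    peak_time,
    pulse_metrics,
    rna_rate,
    simulate,
    steady_state,
)

RATE_GRID = [0.0, 0.01, 0.1, 1.0]


def lsoda_oracle(A, lam, mu, rna0, t_grid):
    """Independent stiff-solver reference for the linear RNA/fuel system."""
    sol = solve_ivp(
        lambda t, y: [A * np.exp(-lam * t) - mu * y[0]],
        (0.0, t_grid[-1]),
        [rna0],
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    return sol.y[0]


class TestRates:
    def test_zero_state_has_zero_rate(self):
        p = KineticParams.from_lumped(1.0, 0.0, 1.0)
        assert rna_rate(ConcentrationState(0.0, 0.0, 0.0), p) == 0.0

    def test_production_minus_degradation(self):
        p = KineticParams(k1=1, t7=1, temp=1, k2=1, rnaseh=1, k3=0, ntp0=2)
        assert rna_rate(ConcentrationState(0.0, rna=1.0, ntp=2.0), p) == pytest.approx(1.0)

    def test_steady_state_balance_gives_zero_rate(self):
        p = KineticParams(k1=0.3, t7=2, temp=1.5, k2=0.2, rnaseh=0.5, ntp0=10)
        rna_ss = p.k1 * p.t7 * p.temp * 10.0 / (p.k2 * p.rnaseh)
        assert rna_rate(ConcentrationState(0.0, rna_ss, 10.0), p) == pytest.approx(0.0)

    def test_fuel_rate_is_nonpositive_and_linear(self):
        p = KineticParams(k3=1, t7=1, temp=1)
        assert ntp_rate(ConcentrationState(0.0, 0.0, 4.0), p) == pytest.approx(-4.0)
        assert ntp_rate(ConcentrationState(0.0, 0.0, 0.0), p) == 0.0
        p0 = KineticParams(k3=0)
        assert ntp_rate(ConcentrationState(0.0, 5.0, 7.0), p0) == 0.0

    def test_negative_concentrations_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationState(0.0, rna=-1.0, ntp=0.0)
        with pytest.raises(ValueError):
            KineticParams(k1=-0.1)


class TestClosedForm:
    def test_initial_value(self):
        p = KineticParams.from_lumped(1.0, 0.1, 0.2, rna0=3.5)
        assert closed_form_rna(p, 0.0) == pytest.approx(3.5)

    def test_pure_production_is_linear(self):
        p = KineticParams.from_lumped(2.0, 0.0, 0.0)
        assert closed_form_rna(p, 3.0) == pytest.approx(6.0)

    def test_distinct_rates_value(self):
        # A=1, lam=1, mu=2 at t=ln2: (e^-t - e^-2t)/(2-1) = 1/2 - 1/4
        p = KineticParams.from_lumped(1.0, 1.0, 2.0)
        assert closed_form_rna(p, math.log(2.0)) == pytest.approx(0.25, rel=1e-12)

    def test_confluent_limit_matches_series_and_ode(self):
        p = KineticParams.from_lumped(1.0, 1.0, 1.0)
        val = closed_form_rna(p, 1.0)
        assert val == pytest.approx(math.exp(-1.0), rel=1e-12)
        t = np.linspace(0, 1, 50)
        assert closed_form_rna(p, t)[-1] == pytest.approx(
            lsoda_oracle(1.0, 1.0, 1.0, 0.0, t)[-1], rel=1e-8
        )

    def test_near_confluent_is_continuous(self):
        base = closed_form_rna(KineticParams.from_lumped(1.0, 0.5, 0.5), 2.0)
        near = closed_form_rna(KineticParams.from_lumped(1.0, 0.5, 0.5 + 1e-12), 2.0)
        assert near == pytest.approx(base, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            closed_form_rna(KineticParams(), -1.0)


class TestSimulate:
    @pytest.mark.parametrize(
        "A,lam,mu",
        [c for c in itertools.product(RATE_GRID, repeat=3)],
    )
    def test_matches_closed_form_over_rate_grid(self, A, lam, mu):
        p = KineticParams.from_lumped(A, lam, mu)
        t = np.linspace(0.0, 20.0, 200)
        traj = simulate(p, t, consume_fuel=True)
        cf = np.asarray(closed_form_rna(p, t))
        scale = max(cf.max(), 1e-12)
        assert np.max(np.abs(traj.rna - cf)) <= 1e-6 * scale

    def test_against_independent_stiff_solver(self):
        p = KineticParams.from_lumped(1.0, 1.0, 2.0)
        t = np.linspace(0.0, math.log(2.0), 101)
        traj = simulate(p, t)
        ref = lsoda_oracle(1.0, 1.0, 2.0, 0.0, t)
        assert traj.rna[-1] == pytest.approx(0.25, rel=1e-6)
        assert np.allclose(traj.rna, ref, rtol=1e-6, atol=1e-9)

    def test_linear_growth_without_decay(self):
        p = KineticParams.from_lumped(1.0, 0.0, 0.0)
        t = np.linspace(0.0, 10.0, 11)
        traj = simulate(p, t, consume_fuel=False)
        assert np.allclose(traj.rna, t, rtol=1e-8)

    def test_plateau_without_fuel_consumption(self):
        p = KineticParams.from_lumped(1.0, 0.0, 1.0)
        traj = simulate(p, np.linspace(0.0, 40.0, 100), consume_fuel=False)
        assert traj.rna[-1] == pytest.approx(1.0, rel=1e-6)
        assert np.all(np.diff(traj.ntp) <= 0.0 + 1e-15)

    def test_transience_with_fuel_limit(self):
        p = KineticParams()
        traj = simulate(p, np.linspace(0.0, 2000.0, 500), consume_fuel=True)
        assert traj.rna[-1] < 0.01 * traj.rna.max()
        assert np.all(traj.rna >= 0)
        assert np.all(np.diff(traj.ntp) <= 1e-12)

    def test_initial_slope_proportional_to_fuel(self):
        import dataclasses

        p1 = dataclasses.replace(KineticParams(), rnaseh=0.0)
        p2 = dataclasses.replace(p1, ntp0=2 * p1.ntp0)
        dt = 1e-4
        s1 = closed_form_rna(p1, dt) / dt
        s2 = closed_form_rna(p2, dt) / dt
        assert s2 == pytest.approx(2.0 * s1, rel=1e-9)

    def test_bad_grids_rejected(self):
        p = KineticParams()
        with pytest.raises(ValueError):
            simulate(p, np.array([1.0, 2.0]))  # must start at 0
        with pytest.raises(ValueError):
            simulate(p, np.array([0.0, 2.0, 1.0]))


class TestSteadyStateAndPeak:
    def test_steady_state_values(self):
        assert steady_state(KineticParams.from_lumped(1.0, 0.0, 1.0)) == pytest.approx(1.0)
        assert steady_state(KineticParams.from_lumped(0.0, 0.0, 0.0)) == 0.0
        assert steady_state(KineticParams.from_lumped(3.0, 0.0, 0.5)) == pytest.approx(6.0)
        assert steady_state(KineticParams.from_lumped(1.0, 0.0, 0.0)) is None

    @pytest.mark.parametrize(
        "lam,mu",
        [(1.0, 2.0), (1.0, 1.0), (0.05, 0.01), (0.3, 0.31)],
    )
    def test_peak_time_matches_grid_search(self, lam, mu):
        p = KineticParams.from_lumped(1.0, lam, mu)
        tp = peak_time(p)
        grid = np.linspace(0.0, 10.0 / min(lam, mu), 400_001)
        t_star = grid[np.argmax(closed_form_rna(p, grid))]
        assert tp == pytest.approx(t_star, abs=grid[1] - grid[0])

    def test_no_peak_without_decay(self):
        assert peak_time(KineticParams.from_lumped(1.0, 0.0, 1.0)) is None
        assert peak_time(KineticParams.from_lumped(1.0, 1.0, 0.0)) is None

    def test_monotone_in_degradation(self, default_params):
        """Peak value, peak time and lifetime all fall as RNaseH rises."""
        import dataclasses

        t = np.arange(0.0, 600.0, 0.25)
        rnaseh_grid = np.linspace(0.06, 0.6, 6)
        peaks, tpeaks, lifetimes = [], [], []
        for rh in rnaseh_grid:
            p = dataclasses.replace(default_params, rnaseh=rh)
            traj = simulate(p, t)
            m = pulse_metrics(traj, 10.0)
            peaks.append(m.peak_value)
            tpeaks.append(peak_time(p))
            lifetimes.append(m.lifetime)
        assert np.all(np.diff(peaks) < 0)
        assert np.all(np.diff(tpeaks) < 0)
        assert np.all(np.diff(lifetimes) < 0)


class TestPulseMetrics:
    def test_below_threshold_not_crossed(self):
        traj = RnaTrajectory(np.arange(5.0), np.full(5, 0.5))
        m = pulse_metrics(traj, 1.0)
        assert not m.crossed and m.lifetime == 0.0

    def test_triangle_pulse_interpolation(self):
        traj = RnaTrajectory(np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0, 0.0]))
        m = pulse_metrics(traj, 1.0)
        assert m.onset_time == pytest.approx(0.5)
        assert m.offset_time == pytest.approx(1.5)
        assert m.lifetime == pytest.approx(1.0)
        assert m.peak_time == pytest.approx(1.0)

    def test_matches_dense_grid_oracle(self):
        p = KineticParams.from_lumped(1.0, 0.02, 0.05)
        coarse = np.linspace(0.0, 400.0, 801)
        dense = np.linspace(0.0, 400.0, 100_001)
        thr = 0.5 * np.max(closed_form_rna(p, dense))
        m = pulse_metrics(simulate(p, coarse), thr)
        above = np.asarray(closed_form_rna(p, dense)) >= thr
        lifetime_oracle = dense[len(above) - 1 - np.argmax(above[::-1])] - dense[np.argmax(above)]
        assert m.lifetime == pytest.approx(lifetime_oracle, rel=0.01)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            RnaTrajectory(np.array([]), np.array([]))


class TestMassBalance:
    def test_no_consumption_zero_residual(self):
        p = KineticParams(k3=0.0)
        traj = simulate(p, np.linspace(0.0, 100.0, 200))
        assert ntp_mass_balance(traj, p) < 1e-12

    def test_fine_grid_residual_small(self):
        p = KineticParams.from_lumped(1.0, 0.1, 0.0)
        traj = simulate(p, np.linspace(0.0, 50.0, 1000))
        assert ntp_mass_balance(traj, p) < 1e-6

    def test_refinement_does_not_worsen(self):
        p = KineticParams()
        coarse = ntp_mass_balance(simulate(p, np.linspace(0.0, 200.0, 10)), p)
        fine = ntp_mass_balance(simulate(p, np.linspace(0.0, 200.0, 1000)), p)
        assert fine <= coarse

    def test_requires_production(self):
        p = KineticParams(k1=0.0)
        traj = simulate(p, np.linspace(0.0, 10.0, 50))
        with pytest.raises(ValueError):
            ntp_mass_balance(traj, p)
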