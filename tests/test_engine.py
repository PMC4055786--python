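"""Solver, dosing-schedule and trajectory behaviour."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pmxsim.engine import (
    DoseRegimen,
    IntegrationError,
    SolverConfig,
    Trajectory,
    dose_times,
    infusion_rate,
    integrate,
    saturable_absorption_rate,
    step,
)
from pmxsim.models import analytic_reference, build_model, transit_chain, two_compartment_oral


def decay(t, y):
    return -y


class TestStep:
    @pytest.mark.parametrize("method,expected", [
        ("euler", 0.9),
        # 4th-order Taylor expansion of exp(-0.1)
        ("rk4", 0.9048375),
    ])
    def test_single_step_of_linear_decay(self, method, expected):
        out = step(method, decay, 0.0, np.array([1.0]), 0.1)
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_rk2_midpoint_second_order(self):
        # midpoint rule on y' = -y: 1 - h + h^2/2
        out = step("rk2", decay, 0.0, np.array([1.0]), 0.1)
        assert out[0] == pytest.approx(1 - 0.1 + 0.005, abs=1e-12)

    def test_zero_rhs_is_identity(self):
        y = np.array([3.0, -2.0])
        for m in ("euler", "rk2", "rk4"):
            assert np.array_equal(step(m, lambda t, y: np.zeros_like(y), 0.0, y, 0.5), y)

    def test_non_finite_derivative_reports_time_and_state(self):
        def bad(t, y):
            return np.array([np.nan])
        with pytest.raises(IntegrationError, match="t=1"):
            step("rk4", bad, 1.0, np.array([1.0]), 0.1)


class TestDoseSchedule:
    def test_daily_dosing_unlimited_within_window(self):
        reg = DoseRegimen(amount=100, first_time=0, interval=24, n_doses=0)
        cfg = SolverConfig(start_time=-1, stop_time=100)
        times = [t for t, _ in dose_times(reg, cfg)]
        assert times == [0, 24, 48, 72, 96]

    def test_dose_count_limits_schedule(self):
        reg = DoseRegimen(amount=100, first_time=0, interval=24, n_doses=3)
        cfg = SolverConfig(start_time=-1, stop_time=100)
        assert [t for t, _ in dose_times(reg, cfg)] == [0, 24, 48]

    def test_lag_shifts_every_dose(self):
        reg = DoseRegimen(amount=100, first_time=0, interval=24, n_doses=3, lag=0.5)
        cfg = SolverConfig(start_time=-1, stop_time=100)
        assert [t for t, _ in dose_times(reg, cfg)] == [0.5, 24.5, 48.5]

    def test_bioavailability_scales_amount(self):
        reg = DoseRegimen(amount=100, n_doses=1, bioavailability=0.5)
        cfg = SolverConfig(start_time=-1, stop_time=10)
        assert dose_times(reg, cfg) == [(0.0, 50.0)]

    def test_empty_schedule_allowed(self):
        reg = DoseRegimen(amount=100, first_time=200, n_doses=1)
        cfg = SolverConfig(start_time=-1, stop_time=100)
        assert dose_times(reg, cfg) == []


class TestInfusion:
    @pytest.mark.parametrize("t,expected", [(1, 7), (25, 7), (-1, 0), (2, 0), (23.5, 0)])
    def test_modulo_window(self, t, expected):
        assert infusion_rate(t, rate=7, duration=2, freq=24) == expected

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            infusion_rate(0, 7, -1, 24)

    def test_integrated_infusion_delivers_rate_times_duration(self):
        # 2 h infusion at 7/h with no elimination accumulates 14 per day
        m = build_model("one_cpt_bolus", ke=0.0)
        reg = DoseRegimen(route="infusion", infusion_rate=7.0,
                          infusion_duration=2.0, interval=24.0,
                          first_time=0.0, target="central")
        cfg = SolverConfig(start_time=-1, stop_time=48, dt=0.01)
        traj = integrate(m, reg, cfg)
        assert np.interp(24, traj.times, traj["central"]) == pytest.approx(14.0, rel=1e-6)
        assert np.interp(48, traj.times, traj["central"]) == pytest.approx(28.0, rel=1e-6)


class TestSaturableAbsorption:
    @pytest.mark.parametrize("depot,expected", [(100, 20), (10, 10), (0, 0)])
    def test_rate_capped_at_absmax(self, depot, expected):
        assert saturable_absorption_rate(depot, ka=1.0, absmax=20.0) == expected


class TestIntegrate:
    def test_bolus_matches_exponential_decay(self, default_config):
        m = build_model("one_cpt_bolus", ke=0.2)
        reg = DoseRegimen(amount=100, n_doses=1, target="central")
        traj = integrate(m, reg, default_config)
        assert np.interp(5.0, traj.times, traj["central"]) == pytest.approx(
            100 * np.exp(-1.0), rel=1e-6)

    def test_no_doses_zero_state_stays_zero(self, default_config):
        m = build_model("one_cpt_oral")
        traj = integrate(m, [], default_config)
        assert np.all(traj["depot"] == 0)
        assert np.all(traj["central"] == 0)

    def test_oral_matches_bateman(self, default_config, single_oral_dose):
        m = build_model("one_cpt_oral", ka=0.1, ke=0.2)
        traj = integrate(m, single_oral_dose, default_config)
        assert np.interp(10.0, traj.times, traj["central"]) == pytest.approx(
            23.254, abs=5e-4)

    def test_unknown_target_compartment(self, default_config):
        m = build_model("one_cpt_oral")
        reg = DoseRegimen(amount=100, n_doses=1, target="gut")
        with pytest.raises(KeyError, match="gut"):
            integrate(m, reg, default_config)

    def test_off_grid_dose_snaps_forward_with_warning(self, caplog):
        m = build_model("one_cpt_bolus", ke=0.0)
        reg = DoseRegimen(amount=10, first_time=0.005, n_doses=1, target="central")
        cfg = SolverConfig(start_time=0, stop_time=1, dt=0.01)
        with caplog.at_level("WARNING"):
            traj = integrate(m, reg, cfg)
        assert "snapped" in caplog.text
        # delivered at the next grid point, 0.01
        i = np.searchsorted(traj.times, 0.01)
        assert traj["central"][i - 1] == 0
        assert traj["central"][i] == 10

    def test_dose_linearity(self, default_config):
        m = build_model("two_cpt_oral")
        for scale in (2.0, 7.5):
            r1 = DoseRegimen(amount=100, interval=24, n_doses=3)
            r2 = DoseRegimen(amount=100 * scale, interval=24, n_doses=3)
            t1 = integrate(m, r1, default_config)
            t2 = integrate(m, r2, default_config)
            for name in m.state_names:
                assert np.allclose(t2[name], scale * t1[name], rtol=1e-12, atol=1e-12)

    def test_rk4_fourth_order_convergence_trend(self, single_oral_dose):
        m = build_model("one_cpt_oral", ka=0.3, ke=0.1)
        ref_times = np.linspace(0, 20, 11)
        sols = []
        for dt in (0.4, 0.2, 0.1):
            cfg = SolverConfig(start_time=-0.4, stop_time=24, dt=dt)
            traj = integrate(m, single_oral_dose, cfg)
            sols.append(np.interp(ref_times, traj.times, traj["central"]))
        d1 = np.max(np.abs(sols[1] - sols[0]))
        d2 = np.max(np.abs(sols[2] - sols[1]))
        assert d2 < d1

    def test_mass_conservation_without_elimination(self):
        m = two_compartment_oral(ka=0.4, ke=0.0, k23=0.3, k32=0.2)
        reg = DoseRegimen(amount=100, interval=24, n_doses=3)
        cfg = SolverConfig(start_time=-1, stop_time=100, dt=0.05)
        traj = integrate(m, reg, cfg)
        total = sum(traj[n] for n in m.state_names)
        administered = np.array([
            sum(a for t, a in dose_times(reg, cfg) if t <= tt + 1e-9)
            for tt in traj.times])
        mask = administered > 0
        assert np.max(np.abs(total[mask] - administered[mask]) / administered[mask]) < 1e-9

    def test_dt_out_subsamples_evenly(self, single_oral_dose):
        m = build_model("one_cpt_oral")
        cfg = SolverConfig(start_time=-1, stop_time=10, dt=0.02, dt_out=0.5)
        traj = integrate(m, single_oral_dose, cfg)
        assert np.allclose(np.diff(traj.times), 0.5)
        assert traj.times[0] == -1 and traj.times[-1] == pytest.approx(10)

    def test_adaptive_stiff_matches_analytic_bolus(self):
        m = build_model("one_cpt_bolus", ke=0.2)
        reg = DoseRegimen(amount=100, n_doses=1, target="central")
        cfg = SolverConfig(start_time=-1, stop_time=30, method="adaptive_stiff",
                           tolerance=1e-8, dt_min=1e-10, dt_max=1.0, dt_out=0.5)
        traj = integrate(m, reg, cfg)
        mask = traj.times >= 0
        ana = analytic_reference("one_cpt_bolus", {"dose": 100, "ke": 0.2},
                                 traj.times[mask])
        assert np.allclose(traj["central"][mask], ana, rtol=1e-5)

    def test_adaptive_stiff_applies_repeated_boluses(self):
        m = build_model("one_cpt_bolus", ke=0.0)
        reg = DoseRegimen(amount=50, first_time=0, interval=10, n_doses=3,
                          target="central")
        cfg = SolverConfig(start_time=-1, stop_time=25, method="adaptive_stiff",
                           tolerance=1e-6, dt_min=1e-10, dt_max=1.0)
        traj = integrate(m, reg, cfg)
        assert traj["central"][-1] == pytest.approx(150.0, rel=1e-9)

    def test_multisubject_states_broadcast(self):
        ka = np.array([0.1, 0.2, 0.4])
        m = build_model("one_cpt_oral", ka=ka, ke=0.1)
        reg = DoseRegimen(amount=100, n_doses=1)
        cfg = SolverConfig(start_time=-1, stop_time=24, dt=0.05)
        traj = integrate(m, reg, cfg,
                         init_state={"depot": np.zeros(3), "central": np.zeros(3)})
        assert traj["central"].shape == (len(traj.times), 3)
        # faster absorption -> higher early concentration
        early = np.interp(2.0, traj.times, traj["central"][:, 0]), \
            np.interp(2.0, traj.times, traj["central"][:, 2])
        assert early[1] > early[0]


class TestTrajectory:
    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 0.0, 1.0]),
                       states={"x": np.zeros(3)})

    def test_frame_has_time_first_and_expanded_subjects(self):
        tr = Trajectory(times=np.array([0.0, 1.0]),
                        states={"x": np.arange(4.0).reshape(2, 2)})
        df = tr.to_frame()
        assert list(df.columns) == ["time", "x_1", "x_2"]


class TestSolverConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"start_time": 5, "stop_time": 5},
        {"dt": 0},
        {"dt_min": 1.0, "dt_max": 0.1},
        {"dt_out": -1},
        {"method": "rk9"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)


@given(dt=st.floats(0.001, 1.0), ke=st.floats(0.0, 1.0))
def test_single_euler_step_matches_closed_form(dt, ke):
    out = step("euler", lambda t, y: -ke * y, 0.0, np.array([1.0]), dt)
    assert out[0] == pytest.approx(1.0 - ke * dt, rel=1e-12)
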