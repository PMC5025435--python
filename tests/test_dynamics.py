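"""Particle transport: low-point geometry, slip law, integration, outcomes."""

import math
from dataclasses import replace

import numpy as np
import pytest

from canalith import (
    ManeuverSpec,
    build_trace,
    classify,
    integrate,
    lowest_point,
    settling_velocity,
    slip_rate,
)
from canalith.errors import InvalidParameterError


def maneuver(alpha=20.0, v=90.0, tp=5.0, tobs=600.0, **kw):
    return ManeuverSpec(
        extension_angle_deg=alpha,
        maneuver_velocity_deg_s=v,
        resting_time_s=tp,
        final_observation_s=tobs,
        **kw,
    )


class TestLowestPoint:
    def test_upright_low_point_is_58_deg_from_ampulla(self, canal):
        assert lowest_point(canal, 0.0) == pytest.approx(58.0)

    def test_rigid_rotation_shifts_low_point_by_beta(self, canal):
        assert lowest_point(canal, 110.0) == pytest.approx(168.0)
        assert lowest_point(canal, -110.0) == pytest.approx(-52.0)  # unclamped

    def test_other_ampulla_elevation(self):
        from canalith import CanalGeometry

        tilted = CanalGeometry(upright_ampulla_elevation_deg=21.0)
        assert lowest_point(tilted, 0.0) == pytest.approx(69.0)


class TestSlipRate:
    def test_zero_at_low_point_and_apex_max_in_between(self, canal, model_materials):
        trace = build_trace(maneuver(tp=30.0, tobs=60.0))
        t_rest = trace.segments[1].t0 + 1.0
        bottom = 168.0
        args = (t_rest, trace, canal, model_materials)
        assert slip_rate(bottom, *args) == pytest.approx(0.0, abs=1e-12)
        assert slip_rate(bottom - 180.0, *args) == pytest.approx(0.0, abs=1e-9)
        v_s = settling_velocity(model_materials)
        expected = math.degrees(v_s / canal.major_radius)
        assert slip_rate(bottom - 90.0, *args) == pytest.approx(expected, rel=1e-9)
        # drag correction scales the rate down linearly
        assert slip_rate(
            bottom - 90.0, *args, drag_correction=4.0
        ) == pytest.approx(expected / 4.0, rel=1e-9)


class TestIntegrate:
    def test_particle_at_equilibrium_stays_during_rest(self, canal, model_materials):
        trace = build_trace(maneuver(tp=60.0, tobs=30.0))
        traj = integrate(canal, model_materials, 4.0, trace, 58.0, record_step=0.05)
        rest_mask = traj.phase == "rest"
        psi_rest = traj.psi_deg[rest_mask]
        # approach to the rest-phase low point (168 deg) is monotone
        gaps = np.abs(psi_rest - 168.0)
        assert np.all(np.diff(gaps) <= 1e-9)
        # and after a long rest the particle is essentially settled
        assert gaps[-1] < 1.5

    def test_unsuccessful_then_successful_at_matching_resting_times(
        self, canal, model_materials, drag_lambda
    ):
        """Short rest drops the particle into the ampulla, long rest into the utricle."""
        for tp, expected in [(5.0, "failure"), (45.0, "success")]:
            trace = build_trace(maneuver(alpha=20.0, v=135.0, tp=tp))
            traj = integrate(canal, model_materials, drag_lambda, trace, 58.0)
            assert classify(traj) == expected

    def test_no_extension_fails_even_with_long_rest_and_fast_movement(
        self, canal, model_materials, drag_lambda
    ):
        """With movements only to the horizontal the settled particle sits exactly
        on the final apex, so any finite-speed second movement loses it to the
        ampulla side."""
        for tp in (10.0, 60.0, 300.0):
            for v in (90.0, 720.0):
                trace = build_trace(maneuver(alpha=0.0, v=v, tp=tp))
                traj = integrate(canal, model_materials, drag_lambda, trace, 58.0)
                assert classify(traj) == "failure", (tp, v)

    def test_fully_settled_margin_beyond_final_apex(self, canal, model_materials):
        """After a very long rest the particle's margin past the final apex is
        2*alpha_plus minus the slip lost during movement 2."""
        lam = 4.0
        alpha = 20.0
        trace = build_trace(maneuver(alpha=alpha, v=90.0, tp=900.0, tobs=1.0))
        traj = integrate(canal, model_materials, lam, trace, 58.0)
        end_m2 = traj.phase_end_psi_deg["move2"]
        apex = lowest_point(canal, -(90.0 + alpha)) + 180.0
        margin = end_m2 - apex
        assert 0.0 < margin < 2.0 * alpha
        slip_lost = 2.0 * alpha - margin
        assert 5.0 < slip_lost < 2.0 * alpha  # sizeable but below the full margin

    def test_absorption_recorded_with_time_and_status(
        self, canal, model_materials, drag_lambda
    ):
        trace = build_trace(maneuver(alpha=30.0, v=90.0, tp=60.0))
        traj = integrate(canal, model_materials, drag_lambda, trace, 58.0)
        assert traj.status == "in_utricle"
        assert traj.absorbed_time_s is not None
        assert traj.psi_deg[-1] == pytest.approx(canal.duct_span_deg)
        assert classify(traj) == "success"

    def test_short_observation_leaves_outcome_undecided(
        self, canal, model_materials, drag_lambda
    ):
        trace = build_trace(maneuver(tp=5.0, tobs=0.1))
        traj = integrate(canal, model_materials, drag_lambda, trace, 58.0)
        assert traj.status == "in_duct"
        assert classify(traj) == "undecided"

    def test_tolerance_refinement_changes_positions_below_hundredth_degree(
        self, canal, model_materials
    ):
        trace = build_trace(maneuver(tp=10.0, tobs=1.0))
        kw = dict(record_step=None)
        a = integrate(canal, model_materials, 4.0, trace, 58.0, **kw)
        b = integrate(
            canal, model_materials, 4.0, trace, 58.0, rtol=1e-9, atol=1e-10, **kw
        )
        for phase in ("move1", "rest", "move2"):
            assert abs(a.phase_end_psi_deg[phase] - b.phase_end_psi_deg[phase]) < 0.01

    def test_initial_position_outside_duct_rejected(self, canal, model_materials):
        trace = build_trace(maneuver())
        with pytest.raises(InvalidParameterError):
            integrate(canal, model_materials, 4.0, trace, -5.0)


class TestAgainstBruteForceEuler:
    """Dual-route check: the hybrid analytic/RK integrator against a plain
    fixed-step explicit Euler discretization of the same slip law."""

    @staticmethod
    def euler_outcome(canal, materials, lam, alpha, v, tp, dt=2e-4, tobs=600.0):
        vs = settling_velocity(materials, lam)
        k = vs / canal.major_radius
        stop1 = 90.0 + alpha
        t1 = stop1 / v
        t2 = t1 + tp
        t3 = t2 + (180.0 + 2.0 * alpha) / v
        psi = math.radians(lowest_point(canal, 0.0))
        span = math.radians(canal.duct_span_deg)
        t = 0.0
        while t < t3 + tobs:
            if t < t1:
                beta = v * t
            elif t < t2:
                beta = stop1
            elif t < t3:
                beta = stop1 - v * (t - t2)
            else:
                beta = -stop1
            bottom = math.radians(lowest_point(canal, beta))
            psi += dt * (-k * math.sin(psi - bottom))
            if psi <= 0.0:
                return "failure"
            if psi >= span:
                return "success"
            t += dt
        return "undecided"

    @pytest.mark.parametrize(
        "alpha, v, tp",
        [(30.0, 90.0, 8.5), (30.0, 90.0, 9.5), (20.0, 135.0, 5.0), (20.0, 135.0, 45.0)],
    )
    def test_outcomes_agree(self, canal, model_materials, drag_lambda, alpha, v, tp):
        trace = build_trace(maneuver(alpha=alpha, v=v, tp=tp))
        mine = classify(integrate(canal, model_materials, drag_lambda, trace, 58.0))
        oracle = self.euler_outcome(canal, model_materials, drag_lambda, alpha, v, tp)
        assert mine == oracle


def test_trajectory_csv_columns(tmp_path, canal, model_materials):
    trace = build_trace(maneuver(tp=2.0, tobs=1.0))
    traj = integrate(canal, model_materials, 4.0, trace, 58.0, record_step=0.05)
    p = tmp_path / "traj.csv"
    traj.to_csv(p)
    import pandas as pd

    df = pd.read_csv(p)
    assert list(df.columns) == ["time_s", "psi_deg", "beta_deg", "phase", "status"]
    assert (df["time_s"].diff().dropna() > 0).all()
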