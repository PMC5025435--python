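"""Overdamped canalith transport along the duct under a maneuver.

The particle is described by its arc coordinate ``psi`` (degrees from the
ampulla end) on the duct centreline circle.  In the overdamped Stokes
regime the particle co-moves with the canal except for a slow slip toward
the instantaneous low point of the effective gravity field:

    d(psi)/dt = -(v_s_eff / R) * sin(psi - psi_bottom_eff)

with ``v_s_eff`` the Stokes settling speed rescaled by the magnitude of
the effective gravity (gravity plus the lever-arm inertial acceleration)
and ``psi_bottom_eff`` the arc coordinate of its low point.  The duct
ends are absorbing: reaching ``psi = 0`` leaves the particle in the
ampulla (maneuver failure), reaching ``psi = duct_span`` drops it into
the utricle (success).

Constant-orientation phases have a closed-form solution (the sine
equation integrates to an exponential decay of ``tan(phi/2)``), which the
integrator uses for the rest and final phases; movement phases are
integrated with an adaptive Runge-Kutta scheme with event detection at
the duct ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidParameterError
from .geometry import CanalGeometry
from .kinematics import OrientationTrace, Segment
from .scaling import G_STANDARD, MaterialSpec, settling_velocity

STATUS_IN_DUCT = "in_duct"
STATUS_AMPULLA = "in_ampulla"
STATUS_UTRICLE = "in_utricle"

#: Offset used to resolve the unstable apex equilibrium toward the
#: ampulla side (conservative tie-break: an exactly balanced particle
#: counts as a failure).
_APEX_EPS = 1e-12


def lowest_point(canal: CanalGeometry, beta_deg: float) -> float:
    """Arc coordinate of the gravitationally lowest duct point at orientation beta.

    At upright (``beta = 0``) with the ampulla ``e`` degrees below the
    horizontal the low point lies ``90 - e`` degrees from the ampulla; a
    rigid rotation by ``beta`` (positive toward the first movement) adds
    ``beta`` to that arc coordinate.  The value is returned unclamped and
    may lie outside ``[0, duct_span]``; absorption at the duct ends is the
    integrator's business.
    """
    return 90.0 - canal.upright_ampulla_elevation_deg + beta_deg


def _effective_field(
    seg: Segment,
    t: float,
    canal: CanalGeometry,
    pivot_offset: float,
    gravity: float,
) -> tuple[float, float]:
    """(g_magnitude, psi_bottom_deg) of the effective gravity at time t.

    In the canal frame gravity is ``(-g sin(beta), -g cos(beta))`` and the
    lever-arm inertial acceleration is ``(alpha*L, omega**2*L)``; the low
    point of their sum generalizes :func:`lowest_point`.
    """
    beta, omega, alpha = seg.eval(t)
    br = math.radians(beta)
    om = math.radians(omega)
    al = math.radians(alpha)
    gx = -gravity * math.sin(br) + al * pivot_offset
    gy = -gravity * math.cos(br) + om * om * pivot_offset
    mag = math.hypot(gx, gy)
    if mag == 0.0:
        return 0.0, 0.0
    gamma = math.degrees(math.atan2(gy, gx))
    psi_bottom = -canal.upright_ampulla_elevation_deg - gamma
    return mag, psi_bottom


def slip_rate(
    psi_deg: float,
    t: float,
    trace: OrientationTrace,
    canal: CanalGeometry,
    materials: MaterialSpec,
    drag_correction: float = 1.0,
    pivot_offset: float = 0.0,
    gravity: float = G_STANDARD,
) -> float:
    """Instantaneous slip rate d(psi)/dt in degrees per second."""
    seg = trace.segment_at(t)
    v_s = settling_velocity(materials, drag_correction, gravity)
    mag, psi_bottom = _effective_field(seg, t, canal, pivot_offset, gravity)
    rate_rad = -(v_s * mag / gravity / canal.major_radius) * math.sin(
        math.radians(psi_deg - psi_bottom)
    )
    return math.degrees(rate_rad)


@dataclass
class Trajectory:
    """Canalith arc-position time series with terminal status.

    ``phase_end_psi_deg`` records the particle position at the end of each
    completed phase (the quantities read off the experiment's video
    frames); ``absorbed_time_s`` is the absorption time if the particle
    reached a duct end.
    """

    time_s: np.ndarray
    psi_deg: np.ndarray
    beta_deg: np.ndarray
    phase: np.ndarray
    status: str
    phase_end_psi_deg: dict = field(default_factory=dict)
    absorbed_time_s: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_s) <= 0):
            raise InvalidParameterError("trajectory times must strictly increase")

    @property
    def terminal_psi_deg(self) -> float:
        return float(self.psi_deg[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "psi_deg": self.psi_deg,
                "beta_deg": self.beta_deg,
                "phase": self.phase,
                "status": [STATUS_IN_DUCT] * (len(self.time_s) - 1) + [self.status],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "status": self.status,
            "terminal_psi_deg": self.terminal_psi_deg,
            "absorbed_time_s": self.absorbed_time_s,
            "phase_end_psi_deg": dict(self.phase_end_psi_deg),
        }


def classify(trajectory: Trajectory) -> str:
    """Map a finished trajectory to the maneuver outcome.

    ``success`` if the particle settled in the utricle, ``failure`` if in
    the ampulla, ``undecided`` if it is still inside the duct when the
    trace ends (extend the final observation time in that case).
    """
    if trajectory.status == STATUS_UTRICLE:
        return "success"
    if trajectory.status == STATUS_AMPULLA:
        return "failure"
    return "undecided"


def _wrap_angle(phi: float) -> float:
    """Wrap to (-pi, pi]."""
    phi = math.fmod(phi, 2.0 * math.pi)
    if phi <= -math.pi:
        phi += 2.0 * math.pi
    elif phi > math.pi:
        phi -= 2.0 * math.pi
    return phi


def _relax_phi(phi0: float, k: float, t: np.ndarray | float):
    """Exact solution of d(phi)/dt = -k sin(phi) with phi(0) = phi0, |phi0| < pi."""
    return 2.0 * np.arctan(np.tan(0.5 * phi0) * np.exp(-k * np.asarray(t, float)))


def _crossing_time(phi0: float, phi_c: float, k: float) -> float:
    """Time for |phi| to decay from |phi0| to |phi_c| under the sine relaxation."""
    return math.log(math.tan(0.5 * abs(phi0)) / math.tan(0.5 * abs(phi_c))) / k


class _Integrator:
    def __init__(
        self,
        canal: CanalGeometry,
        materials: MaterialSpec,
        drag_correction: float,
        pivot_offset: float,
        gravity: float,
        rtol: float,
        atol: float,
        record_step: float | None,
    ):
        self.canal = canal
        self.materials = materials
        self.pivot = pivot_offset
        self.g = gravity
        self.rtol = rtol
        self.atol = atol
        self.record_step = record_step
        self.v_s = settling_velocity(materials, drag_correction, gravity)
        self.span_rad = math.radians(canal.duct_span_deg)
        self.times: list[float] = []
        self.psis: list[float] = []  # radians
        self.betas: list[float] = []
        self.phases: list[str] = []

    def _record(self, t: float, x: float, seg: Segment) -> None:
        self.times.append(t)
        self.psis.append(x)
        self.betas.append(seg.eval(t)[0])
        self.phases.append(seg.phase)

    def _record_grid(self, ts: np.ndarray, xs: np.ndarray, seg: Segment) -> None:
        betas, _, _ = seg.eval_array(ts)
        self.times.extend(ts.tolist())
        self.psis.extend(xs.tolist())
        self.betas.extend(betas.tolist())
        self.phases.extend([seg.phase] * len(ts))

    def _rhs(self, seg: Segment):
        scale = self.v_s / self.g / self.canal.major_radius

        def f(t, y):
            mag, psi_bottom = _effective_field(
                seg, t, self.canal, self.pivot, self.g
            )
            return [-scale * mag * math.sin(y[0] - math.radians(psi_bottom))]

        return f

    def _hold_segment(self, seg: Segment, x0: float) -> tuple[float, float | None]:
        """Propagate through a constant-orientation segment analytically.

        Returns (x_end, absorption_time) with absorption_time None if the
        particle stays in the duct.
        """
        duration = seg.duration
        if duration <= 0.0:
            return x0, None
        _, psi_bottom_deg = _effective_field(seg, seg.t0, self.canal, 0.0, self.g)
        b = math.radians(psi_bottom_deg)
        k = self.v_s / self.canal.major_radius
        phi0 = _wrap_angle(x0 - b)
        if abs(abs(phi0) - math.pi) < _APEX_EPS:
            # unstable apex: resolve toward the ampulla side (failure)
            phi0 = math.pi * (1.0 - 1e-9)
        b_adj = x0 - phi0  # representative of the bottom on phi0's branch
        t_abs: float | None = None
        boundary: float | None = None
        if k > 0.0 and phi0 != 0.0:
            if phi0 > 0.0 and b_adj < 0.0 <= x0:
                phi_c = -b_adj
                if phi_c < abs(phi0):
                    t_abs = _crossing_time(phi0, phi_c, k)
                    boundary = 0.0
            elif phi0 < 0.0 and b_adj > self.span_rad >= x0:
                phi_c = self.span_rad - b_adj
                if abs(phi_c) < abs(phi0):
                    t_abs = _crossing_time(phi0, phi_c, k)
                    boundary = self.span_rad
        if t_abs is not None and t_abs <= duration:
            if self.record_step is not None:
                ts = np.arange(seg.t0, seg.t0 + t_abs, self.record_step)[1:]
                xs = b_adj + _relax_phi(phi0, k, ts - seg.t0)
                self._record_grid(ts, xs, seg)
            self._record(seg.t0 + t_abs, boundary, seg)
            return boundary, seg.t0 + t_abs
        x_end = b_adj + float(_relax_phi(phi0, k, duration)) if k > 0 else x0
        if self.record_step is not None:
            ts = np.arange(seg.t0, seg.t1, self.record_step)[1:]
            xs = (
                b_adj + _relax_phi(phi0, k, ts - seg.t0)
                if k > 0
                else np.full_like(ts, x0)
            )
            self._record_grid(ts, xs, seg)
        self._record(seg.t1, x_end, seg)
        return x_end, None

    def _move_segment(self, seg: Segment, x0: float) -> tuple[float, float | None]:
        """Propagate through a movement segment with adaptive RK and events."""
        edges = [seg.t0, *seg.breakpoints(), seg.t1]
        hit_ampulla = lambda t, y: y[0]  # noqa: E731
        hit_utricle = lambda t, y: y[0] - self.span_rad  # noqa: E731
        hit_ampulla.terminal = True
        hit_utricle.terminal = True
        hit_ampulla.direction = -1
        hit_utricle.direction = 1
        x = x0
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a <= 0.0:
                continue
            sol = solve_ivp(
                self._rhs(seg),
                (a, b),
                [x],
                method="RK45",
                rtol=self.rtol,
                atol=self.atol,
                dense_output=True,
                events=[hit_ampulla, hit_utricle],
            )
            if not sol.success:
                raise IntegrationError(
                    f"integration failed in phase {seg.phase}: {sol.message}"
                )
            t_end = sol.t[-1]
            if self.record_step is not None:
                ts = np.arange(a, t_end, self.record_step)[1:]
                if len(ts):
                    self._record_grid(ts, sol.sol(ts)[0], seg)
            if sol.t_events[0].size:
                t_abs = float(sol.t_events[0][0])
                self._record(t_abs, 0.0, seg)
                return 0.0, t_abs
            if sol.t_events[1].size:
                t_abs = float(sol.t_events[1][0])
                self._record(t_abs, self.span_rad, seg)
                return self.span_rad, t_abs
            x = float(sol.y[0, -1])
        self._record(seg.t1, x, seg)
        return x, None

    def run(self, trace: OrientationTrace, psi0_deg: float) -> Trajectory:
        x = math.radians(psi0_deg)
        self._record(0.0, x, trace.segments[0])
        phase_end: dict[str, float] = {}
        status = STATUS_IN_DUCT
        absorbed: float | None = None
        for seg in trace.segments:
            if seg.plateau_speed_deg_s == 0.0:
                x, t_abs = self._hold_segment(seg, x)
            else:
                x, t_abs = self._move_segment(seg, x)
            if t_abs is not None:
                absorbed = t_abs
                status = STATUS_AMPULLA if x <= 0.0 else STATUS_UTRICLE
                break
            phase_end[seg.phase] = math.degrees(x)
        times = np.asarray(self.times)
        # guard against duplicate sample at an exact phase boundary
        keep = np.concatenate(([True], np.diff(times) > 0))
        return Trajectory(
            time_s=times[keep],
            psi_deg=np.degrees(np.asarray(self.psis))[keep],
            beta_deg=np.asarray(self.betas)[keep],
            phase=np.asarray(self.phases, dtype=object)[keep],
            status=status,
            phase_end_psi_deg=phase_end,
            absorbed_time_s=absorbed,
        )


def integrate(
    canal: CanalGeometry,
    materials: MaterialSpec,
    drag_correction: float,
    trace: OrientationTrace,
    psi0_deg: float,
    *,
    pivot_offset: float = 0.0,
    gravity: float = G_STANDARD,
    record_step: float | None = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the canalith's arc position over a maneuver trace.

    Parameters
    ----------
    drag_correction:
        Wall-drag correction lambda (>= 1) applied to the Stokes settling
        velocity; calibrated by the protocol module.
    psi0_deg:
        Initial arc position, inside ``[0, duct_span_deg]``.
    pivot_offset:
        Lever-arm length in metres (0 for the stepper-motor setup).
    record_step:
        Sampling interval of the returned trajectory in seconds; ``None``
        records only phase boundaries (fast path for parameter scans).

    The integration is deterministic for fixed inputs and tolerances.
    Rest and final phases are propagated with the closed-form solution of
    the sine relaxation; movement phases with adaptive RK45 and terminal
    events at the absorbing duct ends.
    """
    if not 0.0 <= psi0_deg <= canal.duct_span_deg:
        raise InvalidParameterError(
            f"psi0_deg must lie in [0, {canal.duct_span_deg}], got {psi0_deg}"
        )
    integ = _Integrator(
        canal,
        materials,
        drag_correction,
        pivot_offset,
        gravity,
        rtol,
        atol,
        record_step,
    )
    return integ.run(trace, psi0_deg)
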