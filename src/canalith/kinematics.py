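"""Parametrized Sémont maneuver as an orientation time series.

The maneuver consists of four phases:

1. ``move1`` — rotation from upright by ``+(90 + alpha_plus)`` degrees,
2. ``rest``  — resting time ``T_p`` on the first side,
3. ``move2`` — rotation by ``-(180 + 2*alpha_plus)`` degrees to the
   opposite side,
4. ``final`` — final observation period.

Orientation ``beta`` is measured in degrees from upright, positive in the
direction of the first movement.  Movements are constant-velocity
plateaus, optionally with symmetric linear acceleration ramps (trapezoidal
velocity profile); the swept angle is independent of the ramp.

When the canal is mounted on a lever arm (pivot a distance ``L`` below the
canal, arm vertical at upright), rotation adds inertial accelerations at
the canal centre: a centrifugal term ``omega**2 * L`` directed from the
pivot toward the canal and a tangential term ``domega/dt * L``
perpendicular to the arm.  :func:`kinematics_at` returns them expressed in
the canal frame, where they take the simple form ``(alpha*L, omega**2*L)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

PHASES = ("move1", "rest", "move2", "final")


@dataclass(frozen=True)
class ManeuverSpec:
    """Parameters of one Sémont maneuver.

    ``pivot_offset_m = 0`` corresponds to the stepper-motor setup (pivot
    at the canal centre); 0.72 m to a lever arm pivoting about the pelvis.
    """

    extension_angle_deg: float  # alpha_plus, [0, 45]
    maneuver_velocity_deg_s: float  # v, (0, 360]
    resting_time_s: float  # T_p, >= 0
    final_observation_s: float = 60.0  # T_obs, > 0
    pivot_offset_m: float = 0.0  # L, >= 0
    ramp_time_s: float = 0.0  # acceleration ramp, >= 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.extension_angle_deg <= 45.0:
            raise InvalidParameterError(
                f"extension_angle_deg must lie in [0, 45], got {self.extension_angle_deg}"
            )
        # upper bound is generous on purpose: stress tests probe
        # non-physiological velocities well above the clinical range
        if not 0.0 < self.maneuver_velocity_deg_s <= 720.0:
            raise InvalidParameterError(
                "maneuver_velocity_deg_s must lie in (0, 720], "
                f"got {self.maneuver_velocity_deg_s}"
            )
        if self.resting_time_s < 0.0:
            raise InvalidParameterError("resting_time_s must be >= 0")
        if not self.final_observation_s > 0.0:
            raise InvalidParameterError("final_observation_s must be > 0")
        if self.pivot_offset_m < 0.0:
            raise InvalidParameterError("pivot_offset_m must be >= 0")
        if self.ramp_time_s < 0.0:
            raise InvalidParameterError("ramp_time_s must be >= 0")


@dataclass(frozen=True)
class Segment:
    """One phase of the maneuver with closed-form kinematics.

    Movement segments use a trapezoidal velocity profile: linear ramp of
    duration ``ramp_s`` up to the signed plateau speed, plateau, symmetric
    ramp down.  Hold segments have zero sweep and speed.
    """

    phase: str
    t0: float
    t1: float
    beta0_deg: float
    sweep_deg: float
    plateau_speed_deg_s: float  # signed; 0 for holds
    ramp_s: float = 0.0

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    @property
    def beta1_deg(self) -> float:
        return self.beta0_deg + self.sweep_deg

    def eval(self, t: float) -> tuple[float, float, float]:
        """Return (beta_deg, omega_deg_s, alpha_deg_s2) at absolute time t."""
        if not self.t0 - 1e-12 <= t <= self.t1 + 1e-12:
            raise InvalidParameterError(
                f"time {t} outside segment [{self.t0}, {self.t1}]"
            )
        if self.plateau_speed_deg_s == 0.0:
            return self.beta0_deg, 0.0, 0.0
        w = self.plateau_speed_deg_s
        tau = self.ramp_s
        tl = min(max(t - self.t0, 0.0), self.duration)
        if tau == 0.0:
            return self.beta0_deg + w * tl, w, 0.0
        if tl < tau:
            return self.beta0_deg + 0.5 * w * tl**2 / tau, w * tl / tau, w / tau
        if tl <= self.duration - tau:
            return self.beta0_deg + w * (tl - 0.5 * tau), w, 0.0
        s = self.duration - tl
        return self.beta1_deg - 0.5 * w * s**2 / tau, w * s / tau, -w / tau

    def eval_array(
        self, t: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized :meth:`eval` over absolute times inside the segment."""
        tl = np.clip(t - self.t0, 0.0, self.duration)
        if self.plateau_speed_deg_s == 0.0:
            z = np.zeros_like(tl)
            return np.full_like(tl, self.beta0_deg), z, z
        w = self.plateau_speed_deg_s
        tau = self.ramp_s
        if tau == 0.0:
            return (
                self.beta0_deg + w * tl,
                np.full_like(tl, w),
                np.zeros_like(tl),
            )
        beta = np.where(
            tl < tau,
            self.beta0_deg + 0.5 * w * tl**2 / tau,
            np.where(
                tl <= self.duration - tau,
                self.beta0_deg + w * (tl - 0.5 * tau),
                self.beta1_deg - 0.5 * w * (self.duration - tl) ** 2 / tau,
            ),
        )
        omega = np.where(
            tl < tau,
            w * tl / tau,
            np.where(tl <= self.duration - tau, w, w * (self.duration - tl) / tau),
        )
        alpha = np.where(
            tl < tau,
            w / tau,
            np.where(tl <= self.duration - tau, 0.0, -w / tau),
        )
        return beta, omega, alpha

    def breakpoints(self) -> list[float]:
        """Interior times where the acceleration is discontinuous."""
        if self.plateau_speed_deg_s == 0.0 or self.ramp_s == 0.0:
            return []
        return [self.t0 + self.ramp_s, self.t1 - self.ramp_s]


def _move_segment(
    phase: str, t0: float, beta0: float, sweep: float, speed: float, ramp: float
) -> Segment:
    if speed <= 0.0:
        raise InvalidParameterError("maneuver velocity must be strictly positive")
    if ramp > 0.0 and abs(sweep) < speed * ramp:
        raise InvalidParameterError(
            "ramp_time too long for the swept angle at this velocity "
            f"(sweep {sweep} deg, plateau {speed} deg/s, ramp {ramp} s)"
        )
    duration = abs(sweep) / speed + ramp
    return Segment(
        phase=phase,
        t0=t0,
        t1=t0 + duration,
        beta0_deg=beta0,
        sweep_deg=sweep,
        plateau_speed_deg_s=math.copysign(speed, sweep),
        ramp_s=ramp,
    )


def make_segments(
    stop1_deg: float,
    stop2_deg: float,
    velocity1_deg_s: float,
    velocity2_deg_s: float,
    resting_time_s: float,
    final_observation_s: float,
    ramp_time_s: float = 0.0,
) -> tuple[Segment, ...]:
    """Build the four maneuver segments from explicit (possibly perturbed) angles.

    ``stop1_deg`` is the orientation after movement 1 (nominally
    ``+(90 + alpha_plus)``), ``stop2_deg`` the orientation after movement 2
    (nominally ``-(90 + alpha_plus)``).  Used directly by the synthetic
    operator, where the two stops and speeds are jittered independently.
    """
    m1 = _move_segment("move1", 0.0, 0.0, stop1_deg, velocity1_deg_s, ramp_time_s)
    rest = Segment("rest", m1.t1, m1.t1 + resting_time_s, stop1_deg, 0.0, 0.0)
    m2 = _move_segment(
        "move2", rest.t1, stop1_deg, stop2_deg - stop1_deg, velocity2_deg_s, ramp_time_s
    )
    final = Segment("final", m2.t1, m2.t1 + final_observation_s, stop2_deg, 0.0, 0.0)
    return (m1, rest, m2, final)


@dataclass
class OrientationTrace:
    """Sampled orientation/velocity/acceleration time series of a maneuver.

    Samples lie on a uniform grid of ``sample_step_s``; the underlying
    piecewise-analytic segments are retained so downstream consumers can
    evaluate the kinematics exactly between samples.
    """

    segments: tuple[Segment, ...]
    sample_step_s: float = 1e-3
    _arrays: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def duration(self) -> float:
        return self.segments[-1].t1

    def segment_at(self, t: float) -> Segment:
        if not -1e-12 <= t <= self.duration + 1e-12:
            raise InvalidParameterError(
                f"time {t} outside trace span [0, {self.duration}]"
            )
        for seg in self.segments:
            if t <= seg.t1 or seg is self.segments[-1]:
                return seg
        raise AssertionError("unreachable")

    def _sample(self) -> None:
        if self._arrays:
            return
        n = int(math.floor(self.duration / self.sample_step_s)) + 1
        t = np.arange(n) * self.sample_step_s
        beta = np.empty(n)
        omega = np.empty(n)
        alpha = np.empty(n)
        phase = np.empty(n, dtype=object)
        i = 0
        for seg in self.segments:
            j = n if seg is self.segments[-1] else int(
                np.searchsorted(t, seg.t1, side="right")
            )
            beta[i:j], omega[i:j], alpha[i:j] = seg.eval_array(t[i:j])
            phase[i:j] = seg.phase
            i = j
        self._arrays = {
            "time_s": t,
            "beta_deg": beta,
            "omega_deg_s": omega,
            "alpha_deg_s2": alpha,
            "phase": phase,
        }

    @property
    def time_s(self) -> np.ndarray:
        self._sample()
        return self._arrays["time_s"]

    @property
    def beta_deg(self) -> np.ndarray:
        self._sample()
        return self._arrays["beta_deg"]

    @property
    def omega_deg_s(self) -> np.ndarray:
        self._sample()
        return self._arrays["omega_deg_s"]

    @property
    def alpha_deg_s2(self) -> np.ndarray:
        self._sample()
        return self._arrays["alpha_deg_s2"]

    @property
    def phase(self) -> np.ndarray:
        self._sample()
        return self._arrays["phase"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "beta_deg": self.beta_deg,
                "omega_deg_s": self.omega_deg_s,
                "alpha_deg_s2": self.alpha_deg_s2,
                "phase": self.phase,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_trace(spec: ManeuverSpec, sample_step: float = 1e-3) -> OrientationTrace:
    """Realize a maneuver spec as an orientation trace.

    With ``ramp_time_s = 0`` each movement is constant velocity with
    duration ``angle / velocity``; movement 1 sweeps ``90 + alpha_plus``
    degrees, movement 2 ``-(180 + 2*alpha_plus)``.
    """
    if not 0.0 < sample_step <= 0.01:
        raise InvalidParameterError("sample_step must lie in (0, 0.01] s")
    stop1 = 90.0 + spec.extension_angle_deg
    segments = make_segments(
        stop1_deg=stop1,
        stop2_deg=-stop1,
        velocity1_deg_s=spec.maneuver_velocity_deg_s,
        velocity2_deg_s=spec.maneuver_velocity_deg_s,
        resting_time_s=spec.resting_time_s,
        final_observation_s=spec.final_observation_s,
        ramp_time_s=spec.ramp_time_s,
    )
    return OrientationTrace(segments=segments, sample_step_s=sample_step)


def kinematics_at(
    trace: OrientationTrace, t: float, pivot_offset: float = 0.0
) -> tuple[float, float, float, np.ndarray]:
    """Rigid-body kinematics at the canal centre at time ``t``.

    Returns ``(beta_deg, omega_deg_s, alpha_deg_s2, inertial_accel)``
    where ``inertial_accel`` is the 2-vector of inertial (pseudo)
    acceleration in the canal frame, m/s^2: ``(alpha * L, omega**2 * L)``
    with ``omega`` and ``alpha`` in rad/s.  Zero when the pivot coincides
    with the canal centre (``pivot_offset = 0``) or while at rest.
    """
    seg = trace.segment_at(t)
    beta, omega, alpha = seg.eval(min(max(t, seg.t0), seg.t1))
    om = math.radians(omega)
    al = math.radians(alpha)
    inertial = np.array([al * pivot_offset, om * om * pivot_offset])
    return beta, omega, alpha, inertial


def net_rotation_deg(trace: OrientationTrace) -> float:
    """Net orientation change over the whole trace (end minus start)."""
    return trace.segments[-1].beta1_deg - trace.segments[0].beta0_deg
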