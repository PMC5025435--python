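"""Synthetic noisy operator for manually performed lever-arm maneuvers.

A hand-driven lever arm never reproduces a maneuver exactly: the stop
angles, the angular velocity, and the resting time all vary a little
between repetitions.  This module generates reproducible jittered
orientation traces emulating that variability, and implements the
consecutive-repetition decision rule used to call a configuration
successful or unsuccessful near the critical resting time.

Noise model
-----------
Stop angles, movement velocities (as a relative factor), and the resting
time receive independent truncated-normal jitter (clipped at +/- 3 SD).
Mechanical stops on the lever bound gross overshoot of the stop angles;
they are placed a small clearance beyond the nominal angle (default: the
3-SD truncation bound), so realized stop angles remain approximately
normal while never exceeding the stop.  Manual movements always have a
finite acceleration ramp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .kinematics import ManeuverSpec, OrientationTrace, make_segments

SUCCESS = "success"
FAILURE = "failure"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class OperatorNoiseSpec:
    """Variability of a human operator driving the lever arm.

    Defaults produce a few-seconds-wide inconclusive band around the
    critical resting time, comparable to the scatter of manually
    performed maneuvers.
    """

    stop_angle_sd_deg: float = 2.0
    velocity_fraction_sd: float = 0.10
    resting_time_sd_s: float = 0.5
    ramp_time_s: float = 0.15
    seed: int = 0
    #: Clearance of the mechanical stop beyond the nominal stop angle, in
    #: degrees.  None places it at the 3-SD truncation bound.
    stop_clearance_deg: float | None = None

    def __post_init__(self) -> None:
        for name in ("stop_angle_sd_deg", "velocity_fraction_sd", "resting_time_sd_s"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.velocity_fraction_sd >= 1.0 / 3.0:
            raise InvalidParameterError(
                "velocity_fraction_sd must be < 1/3 so jittered velocities stay positive"
            )
        if self.ramp_time_s < 0:
            raise InvalidParameterError("ramp_time_s must be >= 0")

    @property
    def effective_stop_clearance_deg(self) -> float:
        if self.stop_clearance_deg is not None:
            return self.stop_clearance_deg
        return 3.0 * self.stop_angle_sd_deg


def _truncated_normal(rng: np.random.Generator, sd: float) -> float:
    """One draw from N(0, sd^2) truncated at +/- 3 sd."""
    if sd == 0.0:
        return 0.0
    while True:
        x = rng.normal(0.0, sd)
        if abs(x) <= 3.0 * sd:
            return float(x)


def sample_manual_trace(
    spec: ManeuverSpec,
    noise: OperatorNoiseSpec,
    replicate_index: int,
    sample_step: float = 1e-3,
) -> OrientationTrace:
    """Generate one jittered lever-arm maneuver trace.

    The random stream is keyed on ``(noise.seed, replicate_index)``:
    identical inputs reproduce the trace bit for bit, and replicates are
    statistically independent.  With all SDs zero the trace equals the
    ideal :func:`~canalith.kinematics.build_trace` output with the
    operator's ramp time.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(noise.seed), int(replicate_index)]))
    nominal = 90.0 + spec.extension_angle_deg
    cap = nominal + noise.effective_stop_clearance_deg
    # fixed draw order keeps the stream stable across releases
    e1 = _truncated_normal(rng, noise.stop_angle_sd_deg)
    e2 = _truncated_normal(rng, noise.stop_angle_sd_deg)
    eta1 = _truncated_normal(rng, noise.velocity_fraction_sd)
    eta2 = _truncated_normal(rng, noise.velocity_fraction_sd)
    zeta = _truncated_normal(rng, noise.resting_time_sd_s)
    stop1 = min(nominal + e1, cap)
    stop2 = -min(nominal + e2, cap)
    segments = make_segments(
        stop1_deg=stop1,
        stop2_deg=stop2,
        velocity1_deg_s=spec.maneuver_velocity_deg_s * (1.0 + eta1),
        velocity2_deg_s=spec.maneuver_velocity_deg_s * (1.0 + eta2),
        resting_time_s=max(0.0, spec.resting_time_s + zeta),
        final_observation_s=spec.final_observation_s,
        ramp_time_s=noise.ramp_time_s,
    )
    return OrientationTrace(segments=segments, sample_step_s=sample_step)


def consecutive_decision(outcomes, k: int = 3) -> str:
    """Apply the k-consecutive-repetition decision rule to ordered outcomes.

    Scanning left to right, the first completed run of ``k`` identical
    outcomes decides (success or failure), mirroring sequential
    experimental practice; a list with no such run is inconclusive.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    outcomes = list(outcomes)
    if not outcomes:
        raise InvalidParameterError("outcomes must be a non-empty sequence")
    run_value: str | None = None
    run_length = 0
    for o in outcomes:
        if o not in (SUCCESS, FAILURE):
            raise InvalidParameterError(
                f"outcomes must be '{SUCCESS}' or '{FAILURE}', got {o!r}"
            )
        if o == run_value:
            run_length += 1
        else:
            run_value, run_length = o, 1
        if run_length >= k:
            return run_value
    return INCONCLUSIVE
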