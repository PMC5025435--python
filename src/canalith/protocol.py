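"""Experimental campaign: critical-time scans, calibration, and recommendations.

The campaign mirrors the bench protocol: start with the particle settled
at the lowest point of the upright canal, run a parametrized maneuver,
and call it successful if the particle ends in the utricle.  For each
configuration the resting time is scanned upward (from 5 s in 1 s steps)
until the first success; the boundary is then refined by bisection.  The
single free model parameter — the wall-drag correction lambda — is
calibrated on exactly one configuration and every other prediction is
made with that value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import classify, integrate, lowest_point
from .errors import CalibrationError, InvalidParameterError
from .geometry import CanalGeometry
from .kinematics import ManeuverSpec, build_trace
from .operator import (
    INCONCLUSIVE,
    SUCCESS,
    OperatorNoiseSpec,
    consecutive_decision,
    sample_manual_trace,
)
from .scaling import G_STANDARD, MaterialSpec

#: Table of bench configurations: (setup, particle diameter um,
#: extension angle deg, maneuver velocity deg/s).
DEFAULT_CELLS = tuple(
    [("stepper", 180, 20, v) for v in (90, 135, 180)]
    + [("stepper", 250, a, v) for a in (0, 10, 20, 30) for v in (90, 135, 180)]
    + [("lever", 250, 20, v) for v in (90, 135, 180)]
)

LEVER_ARM_M = 0.72


@dataclass(frozen=True)
class ExperimentConfig:
    """One experimental configuration (geometry, materials, maneuver template).

    ``maneuver.resting_time_s`` in the template is a placeholder; scans
    substitute the probed resting time.  ``noise=None`` selects the
    deterministic (stepper-like) mode, a noise spec the stochastic
    manual-operator mode.
    """

    canal: CanalGeometry
    materials: MaterialSpec
    drag_correction: float
    maneuver: ManeuverSpec
    noise: OperatorNoiseSpec | None = None
    gravity: float = G_STANDARD

    @property
    def setup(self) -> str:
        return "lever" if self.maneuver.pivot_offset_m > 0 else "stepper"


@dataclass
class CriticalTimeResult:
    """Outcome of a resting-time scan for one configuration.

    ``critical_time_s`` is None when no success occurred within the scan
    bound.  In stochastic mode ``inconclusive_onset_s`` marks the first
    resting time with at least one observed success (the lower edge of
    the inconclusive band); the decided critical time is the first
    resting time where the consecutive rule returns success.
    """

    critical_time_s: float | None
    history: list = field(default_factory=list)
    mode: str = "deterministic"
    inconclusive_onset_s: float | None = None
    decision_rule: dict = field(default_factory=dict)
    scan_start_s: float = 5.0
    scan_step_s: float = 1.0

    @property
    def reported_s(self) -> float | None:
        """Critical time as the bench protocol reports it.

        The experiment scans the resting time upward on a grid and reports
        the first successful value, so the reported time is the refined
        critical time rounded up to the scan grid (never below the scan
        start).
        """
        if self.critical_time_s is None:
            return None
        n = math.ceil((self.critical_time_s - self.scan_start_s) / self.scan_step_s - 1e-9)
        return float(self.scan_start_s + self.scan_step_s * max(0, n))


def run_maneuver(
    config: ExperimentConfig,
    resting_time_s: float,
    replicate_index: int | None = None,
    record_step: float | None = None,
):
    """Run one maneuver and return its trajectory.

    Deterministic unless ``replicate_index`` is given together with a
    noise spec, in which case the trace is a jittered manual one.
    """
    spec = replace(config.maneuver, resting_time_s=resting_time_s)
    if config.noise is not None and replicate_index is not None:
        trace = sample_manual_trace(spec, config.noise, replicate_index)
    else:
        trace = build_trace(spec)
    psi0 = lowest_point(config.canal, 0.0)
    return integrate(
        config.canal,
        config.materials,
        config.drag_correction,
        trace,
        psi0,
        pivot_offset=config.maneuver.pivot_offset_m,
        gravity=config.gravity,
        record_step=record_step,
    )


def _outcome(config: ExperimentConfig, t_p: float, replicate: int | None = None) -> str:
    out = classify(run_maneuver(config, t_p, replicate))
    if out == "undecided":
        raise RuntimeError(
            f"maneuver outcome undecided at T_p={t_p}s: the particle was still "
            "inside the duct when the trace ended; extend final_observation_s"
        )
    return out


def find_critical_time(
    config: ExperimentConfig,
    start: float = 5.0,
    step: float = 1.0,
    max_time: float = 300.0,
    refine_to: float = 0.1,
    k_consecutive: int = 3,
    max_replicates: int = 12,
) -> CriticalTimeResult:
    """Scan the resting time upward for the shortest successful value.

    Deterministic mode exploits outcome monotonicity twice: a failure at
    the scan bound proves failure everywhere below it, and the first
    scanned success is refined by bisection down to ``refine_to``.
    Stochastic mode generates manual replicates at each resting time and
    applies the consecutive-repetition rule (no sub-step refinement; the
    scan grid is the experiment's resolution).
    """
    if start < 0 or step <= 0:
        raise InvalidParameterError("start must be >= 0 and step > 0")
    if config.noise is None:
        return _find_critical_deterministic(config, start, step, max_time, refine_to)
    return _find_critical_stochastic(
        config, start, step, max_time, k_consecutive, max_replicates
    )


def _find_critical_deterministic(config, start, step, max_time, refine_to):
    history: list[tuple[float, str]] = []
    # monotonicity fast path: if the longest allowed rest fails, all do
    top = _outcome(config, max_time)
    history.append((max_time, top))
    if top != SUCCESS:
        return CriticalTimeResult(
            None, history, "deterministic", scan_start_s=start, scan_step_s=step
        )
    hi = None
    lo = 0.0
    t = start
    while t < max_time:
        out = _outcome(config, t)
        history.append((t, out))
        if out == SUCCESS:
            hi = t
            break
        lo = t
        t += step
    if hi is None:
        hi = max_time
    while hi - lo > refine_to:
        mid = 0.5 * (lo + hi)
        out = _outcome(config, mid)
        history.append((mid, out))
        if out == SUCCESS:
            hi = mid
        else:
            lo = mid
    return CriticalTimeResult(
        hi,
        history,
        "deterministic",
        decision_rule={"refine_to_s": refine_to},
        scan_start_s=start,
        scan_step_s=step,
    )


def _find_critical_stochastic(config, start, step, max_time, k, max_replicates):
    history: list[tuple[float, str]] = []
    onset = None
    replicate = 0
    t = start
    while t <= max_time:
        outcomes: list[str] = []
        decision = INCONCLUSIVE
        while len(outcomes) < max_replicates:
            outcomes.append(_outcome(config, t, replicate))
            replicate += 1
            decision = consecutive_decision(outcomes, k)
            if decision != INCONCLUSIVE:
                break
        history.append((t, decision, tuple(outcomes)))
        if onset is None and SUCCESS in outcomes:
            onset = t
        if decision == SUCCESS:
            return CriticalTimeResult(
                t,
                history,
                "stochastic",
                inconclusive_onset_s=onset,
                decision_rule={"k_consecutive": k, "max_replicates": max_replicates},
                scan_start_s=start,
                scan_step_s=step,
            )
        t += step
    return CriticalTimeResult(
        None,
        history,
        "stochastic",
        inconclusive_onset_s=onset,
        decision_rule={"k_consecutive": k, "max_replicates": max_replicates},
        scan_start_s=start,
        scan_step_s=step,
    )


def calibrate_drag(
    canal: CanalGeometry,
    materials: MaterialSpec,
    maneuver: ManeuverSpec,
    calibration_cell: tuple[float, float, float] = (250e-6, 30.0, 90.0),
    target_critical_time: float = 9.0,
    bracket: tuple[float, float] = (1.0, 20.0),
    tol_s: float = 0.05,
    max_iter: int = 60,
) -> float:
    """Calibrate the wall-drag correction lambda on a single configuration.

    ``calibration_cell`` is (particle diameter m, extension angle deg,
    velocity deg/s).  The simulated critical time is monotone increasing
    in lambda (more drag, slower settling), so a bisection on lambda
    drives it to ``target_critical_time`` within ``tol_s``.
    """
    d, alpha_plus, velocity = calibration_cell

    def crit(lam: float) -> float | None:
        cfg = ExperimentConfig(
            canal=canal,
            materials=replace(materials, particle_diameter=d),
            drag_correction=lam,
            maneuver=replace(
                maneuver,
                extension_angle_deg=alpha_plus,
                maneuver_velocity_deg_s=velocity,
            ),
        )
        return find_critical_time(cfg, refine_to=tol_s).critical_time_s

    lo, hi = bracket
    c_lo, c_hi = crit(lo), crit(hi)
    if c_lo is not None and abs(c_lo - target_critical_time) <= tol_s:
        return lo
    if c_lo is not None and c_lo > target_critical_time:
        raise CalibrationError(
            f"critical time at lambda={lo} already exceeds the target "
            f"({c_lo:.2f} s > {target_critical_time} s); no bracketing sign change"
        )
    if c_hi is not None and c_hi < target_critical_time:
        raise CalibrationError(
            f"critical time at lambda={hi} is below the target "
            f"({c_hi:.2f} s < {target_critical_time} s); no bracketing sign change"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c = crit(mid)
        if c is not None and abs(c - target_critical_time) <= tol_s:
            return mid
        if c is None or c > target_critical_time:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-4:
            return 0.5 * (lo + hi)
    raise CalibrationError("calibration did not converge within max_iter")


def replicate_bench_table(
    canal: CanalGeometry,
    materials: MaterialSpec,
    maneuver: ManeuverSpec,
    drag_correction: float,
    cells=DEFAULT_CELLS,
    calibration_cell: tuple[float, float, float] = (250e-6, 30.0, 90.0),
    noise: OperatorNoiseSpec | None = None,
    max_time: float = 300.0,
    refine_to: float = 0.1,
) -> pd.DataFrame:
    """Predict the critical resting time for every bench configuration.

    ``cells`` are (setup, D um, alpha_plus deg, v deg/s) tuples.  Lever
    cells use the 0.72 m pivot offset (with a finite ramp so inertial
    terms stay integrable) and, when ``noise`` is given, additionally a
    stochastic scan reporting the decided time and the onset of the
    inconclusive band.  The calibration cell is flagged so evaluations
    can exclude the fitted value.
    """
    rows = []
    for setup, d_um, alpha_plus, velocity in cells:
        pivot = LEVER_ARM_M if setup == "lever" else 0.0
        ramp = maneuver.ramp_time_s
        if setup == "lever" and ramp == 0.0:
            ramp = OperatorNoiseSpec().ramp_time_s
        cfg = ExperimentConfig(
            canal=canal,
            materials=replace(materials, particle_diameter=d_um * 1e-6),
            drag_correction=drag_correction,
            maneuver=replace(
                maneuver,
                extension_angle_deg=alpha_plus,
                maneuver_velocity_deg_s=velocity,
                pivot_offset_m=pivot,
                ramp_time_s=ramp,
            ),
        )
        res = find_critical_time(cfg, max_time=max_time, refine_to=refine_to)
        row = {
            "setup": setup,
            "particle_diameter_um": d_um,
            "extension_angle_deg": alpha_plus,
            "maneuver_velocity_deg_s": velocity,
            "critical_time_s": res.critical_time_s,
            "reported_s": res.reported_s,
            "is_calibration_cell": (
                setup == "stepper"
                and math.isclose(d_um * 1e-6, calibration_cell[0])
                and alpha_plus == calibration_cell[1]
                and velocity == calibration_cell[2]
            ),
        }
        if setup == "lever" and noise is not None:
            sres = find_critical_time(replace(cfg, noise=noise), max_time=max_time)
            row["stochastic_critical_time_s"] = sres.critical_time_s
            row["inconclusive_onset_s"] = sres.inconclusive_onset_s
        rows.append(row)
    return pd.DataFrame(rows)


def _ceil_to(value: float, grain: float) -> float:
    return grain * math.ceil(value / grain - 1e-9)


@dataclass(frozen=True)
class Recommendation:
    """Clinical maneuver recommendation derived from bench-scale results."""

    target_diameter_um: float
    reference_diameter_um: float
    cross_section_multiplier: float
    resting_time_s: float
    resting_time_raw_s: float
    resting_time_low_velocity_s: float | None
    resting_time_low_velocity_raw_s: float | None
    first_movement_deg: float
    second_movement_deg: float
    velocity_deg_s: float
    extension_angle_deg: float


def recommend(
    target_human_otoconia_diameter_um: float,
    reference_table: pd.DataFrame,
    extension_angle_deg: float = 20.0,
    reference_human_diameter_um: float = 50.0,
    velocity_deg_s: float = 135.0,
    low_velocity_deg_s: float = 90.0,
    rounding_grain_s: float = 5.0,
) -> Recommendation:
    """Scale bench critical times to a target human otoconia size.

    Stokes settling speed scales with the particle cross-section, so the
    critical resting time for a target diameter is the bench-equivalent
    reference time multiplied by ``(D_ref / D_target)**2``, rounded up to
    the next ``rounding_grain_s``.  The reference at the recommended
    velocity is taken from the lever-arm row when available (closest to
    clinical practice), the low-velocity fallback from the stepper rows.
    """
    target = target_human_otoconia_diameter_um
    if target < 15.0:
        import warnings

        warnings.warn(
            "otoconia below 15 um are unlikely to be clinically relevant "
            "repositioning targets",
            stacklevel=2,
        )
    if target > reference_human_diameter_um:
        raise InvalidParameterError(
            "target diameter exceeds the reference particle's human equivalent"
        )
    multiplier = (reference_human_diameter_um / target) ** 2

    # the bench particle corresponding to the human reference diameter
    bench_reference_um = reference_human_diameter_um * 5.0

    def _cell(setup: str, velocity: float) -> float | None:
        sel = reference_table[
            (reference_table["setup"] == setup)
            & (reference_table["extension_angle_deg"] == extension_angle_deg)
            & (reference_table["maneuver_velocity_deg_s"] == velocity)
        ]
        if "particle_diameter_um" in sel.columns:
            sel = sel[sel["particle_diameter_um"] == bench_reference_um]
        if sel.empty or pd.isna(sel.iloc[0]["critical_time_s"]):
            return None
        return float(sel.iloc[0]["critical_time_s"])

    ref = _cell("lever", velocity_deg_s)
    if ref is None:
        ref = _cell("stepper", velocity_deg_s)
    if ref is None:
        raise InvalidParameterError(
            "reference table lacks a decided critical time at the recommended velocity"
        )
    raw = ref * multiplier
    low_ref = _cell("stepper", low_velocity_deg_s)
    low_raw = None if low_ref is None else low_ref * multiplier
    return Recommendation(
        target_diameter_um=target,
        reference_diameter_um=reference_human_diameter_um,
        cross_section_multiplier=multiplier,
        resting_time_s=_ceil_to(raw, rounding_grain_s),
        resting_time_raw_s=raw,
        resting_time_low_velocity_s=(
            None if low_raw is None else _ceil_to(low_raw, rounding_grain_s)
        ),
        resting_time_low_velocity_raw_s=low_raw,
        first_movement_deg=90.0 + extension_angle_deg,
        second_movement_deg=180.0 + 2.0 * extension_angle_deg,
        velocity_deg_s=velocity_deg_s,
        extension_angle_deg=extension_angle_deg,
    )
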