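"""Manual lever-arm maneuvers: jitter produces an inconclusive band.

Runs the critical-time scan with the synthetic noisy operator (jittered
stop angles, velocity, and resting time on a 72 cm lever arm) and with
the ideal deterministic kinematics, showing the band of resting times in
which repeated manual maneuvers disagree.
"""

from dataclasses import replace

from canalith import (
    CanalGeometry,
    ExperimentConfig,
    ManeuverSpec,
    MaterialSpec,
    OperatorNoiseSpec,
    calibrate_drag,
    find_critical_time,
)
from canalith.protocol import LEVER_ARM_M

canal = CanalGeometry()
materials = MaterialSpec(27e-6, 945.0, 250e-6, 7800.0)
lever = ManeuverSpec(
    extension_angle_deg=20.0,
    maneuver_velocity_deg_s=90.0,
    resting_time_s=5.0,
    final_observation_s=600.0,
    pivot_offset_m=LEVER_ARM_M,
    ramp_time_s=0.15,
)

lam = calibrate_drag(canal, materials, replace(lever, pivot_offset_m=0.0, ramp_time_s=0.0))
base = ExperimentConfig(canal, materials, lam, lever)

det = find_critical_time(base)
print(f"deterministic lever-arm critical time: {det.critical_time_s:.2f} s "
      f"(grid: {det.reported_s:.0f} s)")

noisy = find_critical_time(replace(base, noise=OperatorNoiseSpec(seed=42)))
print("\nnoisy-operator scan (3 consecutive identical outcomes decide):")
for t_p, decision, outcomes in noisy.history:
    marks = "".join("S" if o == "success" else "F" for o in outcomes)
    print(f"  T_p = {t_p:4.0f} s : {decision:<12} [{marks}]")
print(f"\nfirst resting time with any success : {noisy.inconclusive_onset_s:.0f} s")
print(f"decided critical resting time       : {noisy.critical_time_s:.0f} s")
print("Between those two values the outcome depends on the operator's exact "
      "execution - the inconclusive band seen in manual bench experiments.")
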