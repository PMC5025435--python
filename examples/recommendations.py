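"""From bench critical times to clinical maneuver recommendations.

Replicates the full table of bench critical resting times (stepper and
lever-arm) with the calibrated drag factor, then scales the reference
times to a 25 um human otoconium via the cross-section rule.
"""

from canalith import (
    CanalGeometry,
    ManeuverSpec,
    MaterialSpec,
    calibrate_drag,
    recommend,
    replicate_bench_table,
)

canal = CanalGeometry()
materials = MaterialSpec(27e-6, 945.0, 250e-6, 7800.0)
template = ManeuverSpec(
    extension_angle_deg=20.0,
    maneuver_velocity_deg_s=90.0,
    resting_time_s=5.0,
    final_observation_s=600.0,
)

lam = calibrate_drag(canal, materials, template)
table = replicate_bench_table(canal, materials, template, lam)
print("predicted critical resting times (s), 'X' = no success up to 300 s:\n")
show = table.assign(
    reported=lambda d: d.reported_s.map(lambda x: "X" if x != x else f"{x:.0f}")
)[["setup", "particle_diameter_um", "extension_angle_deg",
   "maneuver_velocity_deg_s", "reported"]]
print(show.to_string(index=False))

rec = recommend(25.0, table)
print(f"\nrecommendation for {rec.target_diameter_um:.0f} um otoconia "
      f"(cross-section multiplier {rec.cross_section_multiplier:.0f}x):")
print(f"  resting time      >= {rec.resting_time_s:.0f} s "
      f"(raw {rec.resting_time_raw_s:.1f} s)")
if rec.resting_time_low_velocity_s is not None:
    print(f"  at 90 deg/s       >= {rec.resting_time_low_velocity_s:.0f} s "
          f"(raw {rec.resting_time_low_velocity_raw_s:.1f} s)")
print(f"  first movement    {rec.first_movement_deg:.0f} deg")
print(f"  second movement   {rec.second_movement_deg:.0f} deg")
print(f"  maneuver velocity ~{rec.velocity_deg_s:.0f} deg/s")
print("Smaller otoconia settle more slowly (speed ~ D^2), hence the longer "
      "resting times compared to the bench particle's human equivalent.")
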