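# Geometrical and physical properties of the scaled bench canal model
# (5x human scale; steel microsphere canalith in a viscous model endolymph).
canal:
  major_radius_mm: 16.0
  duct_radius_mm: 0.75
  duct_span_deg: 240.0
  upright_ampulla_elevation_deg: 32.0
materials:
  fluid_kinematic_viscosity_m2_s: 2.7e-05
  fluid_density_kg_m3: 945.0
  particle_diameter_um: 250.0
  particle_density_kg_m3: 7800.0
  regime: scaled_model
scaling:
  geometric_factor: 5.0
  reference_endolymph_density_kg_m3: 1000.0
  reference_otoconia_density_kg_m3: 2700.0
maneuver:
  extension_angle_deg: 20.0
  maneuver_velocity_deg_s: 90.0
  resting_time_s: 45.0
  final_observation_s: 600.0
  pivot_offset_m: 0.0
  ramp_time_s: 0.0
protocol:
  scan_start_s: 5.0
  scan_step_s: 1.0
  scan_max_s: 300.0
  refine_to_s: 0.1
  calibration:
    particle_diameter_um: 250.0
    extension_angle_deg: 30.0
    maneuver_velocity_deg_s: 90.0
    target_critical_time_s: 9.0
seed: 0
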