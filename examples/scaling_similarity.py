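"""Dynamic-similarity scaling: bench model parameters vs the human canal.

Builds the 5x-scaled bench material spec, checks the similarity rules,
unscales it back to human dimensions, and quantifies how much more slowly
the bench particle settles than its human counterpart.
"""

from canalith import (
    CanalGeometry,
    MaterialSpec,
    model_to_human_settling_slowdown,
    required_density_ratio,
    required_viscosity_factor,
    settling_velocity,
    unscale_model,
)

canal = CanalGeometry()  # R = 16 mm, a = 0.75 mm
bench = MaterialSpec(
    fluid_kinematic_viscosity=27e-6,  # m^2/s
    fluid_density=945.0,  # kg/m^3
    particle_diameter=250e-6,  # m
    particle_density=7800.0,  # kg/m^3 (steel microsphere)
)

f = 5.0
print(f"viscosity factor required at f={f:g}: {required_viscosity_factor(f):g}")
print(f"density ratio required at f={f:g} (human ratio 2.7): "
      f"{required_density_ratio(f, 2.7):g}")

human, human_canal = unscale_model(bench, canal)
print("\nunscaled (human) parameters:")
print(f"  canal radius       {human_canal.major_radius*1e3:.2f} mm")
print(f"  duct radius        {human_canal.duct_radius*1e3:.2f} mm")
print(f"  fluid viscosity    {human.fluid_kinematic_viscosity:.3g} m^2/s")
print(f"  particle diameter  {human.particle_diameter*1e6:.0f} um")
print(f"  particle density   {human.particle_density:.0f} kg/m^3")

v_bench = settling_velocity(bench)
print(f"\nfree-Stokes settling speed of the bench particle: {v_bench*1e3:.2f} mm/s")

# compare against true human otoconia/endolymph values (the bench pairing is
# deliberately imperfect: densities were rounded to available materials)
true_human = MaterialSpec(1e-6, 1000.0, 50e-6, 2700.0, regime="human")
ratio = model_to_human_settling_slowdown(bench, true_human)
print(f"bench/human settling-time ratio: {ratio:.3f}")
print(f"-> the bench particle settles {100*(ratio-1):.0f}% more slowly, so bench "
      "critical times are conservative for the human canal.")
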