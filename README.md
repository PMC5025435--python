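# canalith

Mechanistic simulation of canalith repositioning in a semicircular canal.

Benign paroxysmal positional vertigo (BPPV) is most often caused by
canalolithiasis: otoconia that have detached from the utricular macula and
float freely in a semicircular canal (SCC). The Sémont liberatory maneuver
treats it with two rapid body rotations separated by a resting period,
intended to carry the debris past the apex of the canal and drop it back
into the utricle. Whether the maneuver succeeds depends on how its
parameters interact with the slow gravitational settling of the particle
inside the duct.

`canalith` is an in-silico twin of a 5×-scaled bench model of an SCC with
a single spherical canalith. It is aimed at vestibular-biomechanics
researchers and at anyone designing or teaching repositioning maneuvers
who wants quantitative, reproducible predictions of maneuver success. The
package provides:

* **Parametrized Sémont maneuvers** — extension angle α⁺ beyond the
  horizontal, angular velocity v, resting time T_p — realized as
  orientation traces β(t), including lever-arm kinematics (pivot 72 cm
  below the canal) with centrifugal ω²L and tangential ω̇L inertial terms.
* **Overdamped particle transport** along the duct centreline:
  dψ/dt = −(v_s/R)·sin(ψ − ψ_bottom(t)), where ψ is the arc coordinate
  from the ampulla, ψ_bottom the low point of the effective gravity field,
  and v_s = (ρ_p − ρ_e)·g·D²/(18·ρ_e·ν·λ) the Stokes settling speed with a
  wall-drag correction λ. The duct ends absorb: ampulla = failure,
  utricle = success.
* **Dynamic-similarity scaling** between bench and human parameters:
  viscosity ×f², density ratio 1 + f·(ρ_p/ρ − 1), lengths ×f.
* **The experimental protocol**: critical-resting-time scans (from 5 s in
  1 s steps, refined by bisection), calibration of λ on a single
  configuration, replication of the full bench configuration table, and a
  clinical recommendation engine that rescales critical times to human
  otoconia sizes via the cross-section rule (D_ref/D_target)².
* **A synthetic noisy operator** for manual lever-arm maneuvers, with the
  three-consecutive-repetitions decision rule and the resulting
  inconclusive band around the critical time.

## Worked example

Calibrate the drag correction on the 30° cell and scan the resting time
for the headline configuration (250 µm particle, α⁺ = 20°, 90°/s):

```sh
python examples/critical_time_scan.py
```

```
lambda calibrated on the 30 deg / 90 deg/s cell (9 s): 4.53

  T_p =   5.00 s : failure
  ...
  T_p =  12.00 s : failure
  T_p =  12.19 s : success
  T_p =  13.00 s : success

refined critical resting time : 12.19 s
reported on the 1 s scan grid : 13 s
```

Below the critical resting time the particle has not settled close enough
to the canal's low point, so the second movement fails to carry it past
the apex and it falls back toward the ampulla. The same library calls are
available programmatically:

```python
from canalith import (CanalGeometry, ManeuverSpec, MaterialSpec,
                      ExperimentConfig, calibrate_drag, find_critical_time)

canal = CanalGeometry()                    # R = 16 mm, a = 0.75 mm
materials = MaterialSpec(27e-6, 945.0, 250e-6, 7800.0)
maneuver = ManeuverSpec(extension_angle_deg=20, maneuver_velocity_deg_s=90,
                        resting_time_s=5, final_observation_s=600)
lam = calibrate_drag(canal, materials, maneuver)
result = find_critical_time(ExperimentConfig(canal, materials, lam, maneuver))
print(result.reported_s)                   # 13.0
```

The other scripts in `examples/` cover the similarity scaling, a
successful/unsuccessful maneuver pair, the noisy-operator inconclusive
band, and the recommendation engine. A thin CLI wraps the same calls:

```sh
canalith bench-table            # predict the full configuration table
canalith recommend --target-diameter-um 25
canalith simulate --resting-time 45
```

## Documentation

The model, its assumptions, the calibration strategy, numerical choices
and known limitations are documented in [`docs/methods.md`](docs/methods.md).
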