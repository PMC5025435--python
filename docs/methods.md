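# Methods

## Physical model

The semicircular canal is reduced to a planar circular duct of major
radius `R` (centreline) and slender-duct radius `a ≪ R`. Positions along
the duct are described by a single arc coordinate `ψ` in degrees, with
`ψ = 0` at the ampulla end and `ψ = Ψ` (duct span) at the utricle
opening. The maneuver plane coincides with the canal plane, so the
simulation is strictly two-dimensional; the initial 45° head turn of the
clinical maneuver is absorbed into this in-plane assumption.

A single spherical canalith of diameter `D` and density `ρ_p` sits in a
fluid of density `ρ_e` and kinematic viscosity `ν`. At the relevant
scales inertia is negligible (overdamped Stokes regime): the particle
co-moves rigidly with the canal except for a slow slip toward the
instantaneous low point of the effective gravity field,

```
dψ/dt = −(v_s,eff / R) · sin(ψ − ψ_bottom,eff(t))
v_s   = (ρ_p − ρ_e) · g · D² / (18 · ρ_e · ν · λ)
```

`v_s` is the Stokes terminal velocity with a wall-drag correction
`λ ≥ 1` for a sphere settling along the duct wall; `v_s,eff` rescales it
by `|g_eff|/g`. The effective gravity `g_eff` is gravity plus the
inertial (pseudo) acceleration at the canal centre. In the canal frame

```
g_eff = (−g sinβ + ω̇L,  −g cosβ + ω²L)
```

with `β` the body orientation, `ω` the angular velocity and `L` the
pivot offset (0 for a motor-driven mount whose rotation axis passes
through the canal centre; 0.72 m for a lever arm pivoting about the
pelvis, vertical at upright with the pivot below the canal). The low
point of that field sits at `ψ_bottom = (90° − e) − γ`, where `e` is the
upright ampulla elevation (32°, placing the low point 58° from the
ampulla) and `γ` the field's direction angle; under pure gravity this
reduces to `ψ_bottom = 58° + β`.

The duct ends are absorbing: reaching `ψ = 0` leaves the particle in the
ampulla (maneuver failure), `ψ = Ψ` drops it into the utricle (success).
The fluid is assumed to co-rotate rigidly with the canal (the duct's
viscous spin-up time `a²/ν ≈ 0.02 s` is far below any maneuver time
scale); relative endolymph flow and cupula back-pressure are neglected —
the model is settling-dominated by construction and produces no cupula
displacement or nystagmus output.

### Why the maneuver succeeds or fails

After movement 1 (sweep `90° + α⁺`) the low point sits at `58° + 90° + α⁺`;
the particle relaxes toward it during the resting time `T_p`. Movement 2
(sweep `−(180° + 2α⁺)`) shifts the apex — the unstable equilibrium — to
`ψ_bottom,rest − 2α⁺ + slip`, i.e. a fully settled particle clears the
apex by `2α⁺` minus the slip lost while the canal rotates. At `α⁺ = 0`
the settled particle lands exactly on the apex, so any finite-speed
movement loses it to the ampulla side: extension beyond the horizontal
is structurally necessary, not merely helpful. The critical resting time
is the shortest `T_p` for which the relaxation has progressed far enough
to survive the movement-2 slip loss.

## Dynamic-similarity scaling

A bench model geometrically `f` times larger than the organ reproduces
its settling dynamics on the same time base when the fluid viscosity is
`f²` times the endolymph viscosity and the particle-to-fluid density
ratio is `1 + f·(ρ_p/ρ − 1)` (≈ 9.5 at `f = 5` with the otoconia ratio
2.7). `unscale_model` inverts this mapping (lengths ÷f, viscosity ÷f²,
density ratio pulled back through the affine rule); it is the exact
inverse of `rescale_model` up to the experimenter's free choice of bench
fluid density. Because the bench materials are real substances rather
than exact similarity solutions, the bench particle settles somewhat more
slowly than its human counterpart; the ratio of settling times over
corresponding distances equals `f·v_human/v_model` (≈ 1.27 for the
250 µm ↔ 50 µm pairing), so bench-derived critical times are conservative
when transferred to the human canal.

## Parameters

| parameter | symbol | default | unit | note |
|---|---|---|---|---|
| canal major radius | R | 16e-3 | m | bench scale (human: 3.2 mm) |
| duct radius | a | 0.75e-3 | m | slenderness only; not dynamical |
| duct span | Ψ | 240 | deg | see below |
| ampulla elevation | e | 32 | deg | upright orientation |
| fluid viscosity | ν | 27e-6 | m²/s | bench fluid |
| fluid density | ρ_e | 945 | kg/m³ | bench fluid |
| particle diameter | D | 250e-6 | m | bench steel microsphere |
| particle density | ρ_p | 7800 | kg/m³ | steel |
| gravity | g | 9.81 | m/s² | standard value |
| wall-drag correction | λ | calibrated (≈ 4.5) | – | see calibration |
| extension angle | α⁺ | 0–45 | deg | maneuver parameter |
| maneuver velocity | v | ≤ 720 | deg/s | clinical range 90–180 |
| resting time | T_p | scanned | s | maneuver parameter |
| pivot offset | L | 0 or 0.72 | m | stepper / lever arm |
| ramp time | τ | 0 (stepper), 0.15 (manual) | s | trapezoidal velocity profile |

**Duct span Ψ = 240°.** The span must exceed the post-movement-1 rest
position (168° at α⁺ = 20°) and lie below the post-movement-2
utricle-side equilibrium (≥ 280° for the tested α⁺). Within that window
the choice only moves the absorption point on the success side; the
critical resting time is set by the apex crossing and is insensitive to
Ψ. The bench model's true span is not dimensioned in the source material,
so Ψ is configurable.

**Ramp time.** Motor-driven runs assume ideal constant-velocity movements
(the motor's true acceleration profile is unknown; instantaneous starts
are the simplest assumption and the swept angles are ramp-invariant).
Lever-arm runs — deterministic or noisy — always use a 0.15 s trapezoidal
ramp: a human operator cannot produce velocity jumps, and a finite ramp
keeps the tangential inertial term `ω̇L` integrable rather than
impulsive.

**Apex tie-break.** A particle exactly on the unstable apex is resolved
toward the ampulla (failure). This is the conservative choice and makes
the impossibility at α⁺ = 0 exact rather than marginal.

## Calibration of the wall-drag correction

λ is the model's only free parameter. Free-Stokes drag (λ = 1) gives the
bench particle a settling speed of 9.15 mm/s and a canal relaxation time
`R/v_s ≈ 1.75 s`, which puts every critical resting time far below the
bench observations — consistent with published observations of beads in
real canals settling much more slowly than free Stokes predicts, as
expected for a sphere rolling/sliding on the duct wall. λ is therefore
calibrated on exactly one configuration: the simulated critical time at
(250 µm, α⁺ = 30°, 90°/s) is driven to 9 s by bisection (the critical
time is monotone increasing in λ). The calibrated value is λ ≈ 4.5.
Every other prediction — including the headline (250 µm, 20°, 90°/s)
cell — is made with that single value, so the table replication is a
genuine one-parameter prediction, not a fit. Calibrating instead on the
(20°, 135°/s) cell leaves the predicted ordering of the 250 µm stepper
cells unchanged.

## Protocol semantics

The critical-time scan mirrors the bench procedure: resting times are
probed upward from 5 s in 1 s increments until the first success; the
failure/success boundary is then refined internally by bisection to
0.1 s. Reported values follow the bench convention — the first successful
resting time on the scan grid, i.e. the refined value rounded *up* to the
grid. Scans are bounded at 300 s: a failure at the bound proves (by
outcome monotonicity in `T_p`) failure everywhere below it, and the
configuration is reported as having no critical time. The final
observation phase defaults to 600 s in protocol configurations so that
outcomes arbitrarily close to the critical time are still decided (an
outcome still undecided at trace end raises, with guidance to extend the
observation window).

In stochastic (manual-operator) mode, replicate maneuvers are generated
at each resting time until a run of three consecutive identical outcomes
decides, scanning outcomes left to right as the experiment would
(first completed run wins); twelve replicates without a decision leave
the resting time inconclusive. The decided critical time is the first
resting time decided successful; the first resting time with *any*
success marks the onset of the inconclusive band.

## Synthetic operator

The generator emulates a clinician driving the lever arm by hand.
Stop angles receive additive jitter (SD 2°), movement velocities
multiplicative jitter (SD 10 %), and the resting time additive jitter
(SD 0.5 s); all jitters are truncated normals (±3 SD), independently
drawn per movement and per replicate from a stream keyed on
`(seed, replicate_index)` — identical keys reproduce traces bit for bit.
Mechanical stops bound gross overshoot of the stop angles; they are
placed a small clearance (default: the 3 SD truncation bound) beyond the
nominal angle, so realized stop angles stay approximately normal while
never exceeding the stop. The jitter magnitudes are plausibility choices,
not measured values: they produce a few-seconds-wide inconclusive band
around the critical time, matching the qualitative behaviour of manual
bench experiments. The generator does not model operator learning or
fatigue, sensor noise, or systematic bias between operators — passing
stochastic tests therefore demonstrates the machinery (reproducibility,
band formation, the decision rule), not a validated model of human motor
variability.

## Numerical scheme

Constant-orientation phases (rest, final observation) reduce to the
autonomous equation `dφ/dt = −k sinφ` with `φ = ψ − ψ_bottom`, solved in
closed form via `tan(φ/2) = tan(φ₀/2)·e^(−kt)`; absorption times at the
duct ends are obtained by inverting the same expression. Movement phases
are integrated with adaptive RK45 (`rtol 1e-8`, `atol 1e-9` rad,
sub-split at ramp breakpoints) with terminal event detection at `ψ = 0`
and `ψ = Ψ`. Tightening the tolerances tenfold moves end-of-phase
positions by less than 0.01°. The hybrid integrator is cross-checked in
the test suite against a brute-force fixed-step explicit-Euler
discretization of the same slip law. All internal computation is SI;
degrees/mm/µm appear only at the configuration and CSV surfaces.

Problem sizes: a single maneuver integrates in ~1 ms–10 ms; a full
critical-time scan is tens of maneuvers, the calibration a few hundred,
and the full 18-cell table replication runs in about two seconds on one
core. Stochastic scans use up to 12 replicates per resting time.

## Known limitations

* **Sine-law relaxation tail.** The slip law approaches the low point
  asymptotically (the last degree takes as long as the preceding ten),
  whereas bench particles come visibly to rest in 10–30 s. With λ
  calibrated to the 9 s cell, the simulated time to come within 1° of
  the low point is 37–41 s for the 250 µm particle and ~77 s for the
  180 µm particle. No single constant λ can reconcile both observations
  under this law: matching the settle band requires λ ≈ 1, at which the
  movement-2 slip loss exceeds the `2α⁺` margin and no critical time is
  reproduced at all. The discrepancy suggests the real near-bottom
  dynamics are not pure Stokes slip (e.g. contact friction arrests the
  particle), which the 1-D centreline model deliberately does not
  include.
* **Weaker extension-angle sensitivity than the bench.** The calibrated
  model predicts critical times of ~17–20 s at α⁺ = 10° (bench: 26–33 s,
  with no success at all at 90°/s) and 13 s at the headline 20°/90°/s
  cell (bench: 16 s). The ordering of configurations is reproduced
  exactly within a particle size; across particle sizes the 180 µm row
  ranks slightly below the bench's α⁺ = 10° cells.
* Single spherical particle only; lumps, multiple particles and
  non-spherical debris are out of scope, as are cupula mechanics,
  nystagmus prediction, cupulolithiasis, and 3-D head/trunk kinematics.
* The absolute particle settling time scale (a characteristic fall time
  through a short duct section) depends on a length convention defined
  in prior work; only the bench/human *ratio* of settling times is
  meaningful here.
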