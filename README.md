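# sprainsim

Probabilistic forward-dynamic simulation of lateral ankle inversion
sprains during single-limb drop landing.

Lateral ankle sprains — the foot rolling into excessive supination about
the subtalar joint — are the most common musculoskeletal injury in sport
and military activity. Which factors drive them (drop height, landing
posture, surface incline) and which protect against them (muscular
co-activation, stretch reflexes, passive ankle stiffness, external
bracing) is hard to study experimentally, because injurious trials cannot
ethically be produced on purpose. `sprainsim` provides a desk-scale
computational laboratory for this question: a reduced-order
musculoskeletal landing model wrapped in probabilistic analysis machinery,
for biomechanists and brace designers who want confidence bounds and
sensitivity rankings rather than single deterministic trajectories.

## What is inside

**Landing model** (`sprainsim.landing`). A lumped 68 kg mass drops from
height *h* onto a platform inclined by angle *i* (the surface drops on the
lateral side, forcing inversion). Four degrees of freedom: vertical and
lateral translation of the mass, talocrural rotation (dorsiflexion +)
about a tibia-fixed axis, and subtalar rotation (supination +) about a
talus-fixed oblique axis. The sole meets the ground through an
elastic-foundation contact model (per-point normal force
f = max(0, A·E·δ·(1 + c·δ̇)) with regularised Coulomb friction); passive
ankle stiffness is an uncoupled rotation-only bushing with a
double-exponential torque–angle law, and an optional brace bushing acts in
parallel, scaled as a fraction of passive-anatomy flexibility. Muscles act
on the subtalar axis through a stretch-reflex/co-activation controller
with latency and activation dynamics. Integration is fixed-step RK4;
identical inputs give bit-identical trajectories.

**Kinematics** (`sprainsim.kinematics`). Composition of the two oblique
hinge rotations and post-hoc resolution to the ISB-recommended joint
coordinate system (JCS) of the ankle complex: dorsiflexion about a
tibia-fixed axis, inversion about a floating axis, internal rotation about
the calcaneus y-axis. Supination about the oblique subtalar axis (inclined
38° superior, 9° medial to the anterior foot direction) is *not* the same
angle as JCS inversion — the package converts between conventions, which
matters when comparing simulations against motion-capture or cadaveric
thresholds.

**Probabilistic engine** (`sprainsim.probabilistic`). Ten input parameters
(brace scale, co-activation, reflex gain, muscle strength, passive
flexibility, both contact postures, drop height, contact modulus and
dissipation) carry normal/lognormal/fixed distributions. Monte Carlo
propagation yields empirical CDFs, 5/50/95th percentiles, Pearson
input–response correlations and probabilistic sensitivity factors
(common-random-number derivatives of the response mean and SD with respect
to each input's mean and SD). The advanced mean value (AMV) method gives
the same percentile estimates from a handful of model runs: one evaluation
at the mean, one per variable input for a standard-normal-space gradient,
and one fresh evaluation at the most probable point u\* = Φ⁻¹(p)·α per
probability level — 14 evaluations for 10 inputs at three levels. The
normalised gradient α ranks input importance.

**Study runner and CLI** (`sprainsim.study`, `sprain-sim`). Six built-in
study designs (level vs 30° inclined landing, with combinations of
co-activation, reflexes and bracing fixed at zero or variable) plus
YAML-configurable custom studies, with JSON/CSV reports whose summaries
are recomputable from the stored raw trials.

## Worked example

```python
import sprainsim as ss

inp = ss.SimulationInputs(incline_deg=30.0, drop_height_m=0.30,
                          talocrural_contact_deg=34.0)
traj = ss.simulate_drop_landing(inp)
out = ss.extract_peak_outcomes(traj)
print(out.peak_subtalar_supination_deg, out.peak_jcs_inversion_deg)
print(ss.supination_for_inversion(35.0, 20.0))
```

prints (0.30 m drop onto a 30° incline, no muscle input, no brace):

```
peak subtalar supination :   46.0 deg at t = 0.293 s
peak JCS inversion       :   32.5 deg
peak talocrural angle    :   15.8 deg (dorsiflexion +)
passive moment (subtalar):  -22.5 N m at the peak instant
supination for 35 deg JCS inversion at 20 deg plantarflexion: 50.6 deg
```

The unprotected landing rolls to 46° supination with ~22 N m borne by the
passive bushing; in JCS terms this is only about 33° of inversion. The
last line is the cross-convention solve: reaching the ~35° JCS-inversion
range where cadaveric studies place lateral-ligament damage requires
roughly 51° of supination about the oblique subtalar axis when the foot is
20° plantarflexed.

From the shell, the full-mix probabilistic study (brace 150 ± 6%,
co-activation 20 ± 5%, reflex gain 5 ± 1 on a 30° incline):

```sh
$ sprain-sim run --study 6 --method amv --seed 42 --out out/amv6
study 6 (amv) -> out/amv6
  peak_subtalar_supination_deg p5: amv=23.31 (first-order 28.91)
  peak_subtalar_supination_deg p50: amv=31.26 (first-order 31.26)
  peak_subtalar_supination_deg p95: amv=33.03 (first-order 33.61)
  model evaluations: 14
```

Fourteen simulations bound the peak-supination distribution: the median
trial peaks near 31° and 9 in 10 trials fall between about 23° and 33°.
`--method mc --trials 1000` computes the same percentiles by brute force,
along with the correlation table (`sensitivities.csv`) ranking which
inputs drive the outcome.

## Limitations

The model is deliberately reduced: no knee/hip energy absorption, no
muscle-path geometry, a four-point rigid sole, and torque-level muscle
control. It reproduces directions of effect and the scale of reported
sprain mechanics, not subject-specific magnitudes; see `docs/methods.md`
for the model equations, parameter choices, and known limitations.
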