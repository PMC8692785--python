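# Methods

## Scope and model structure

`sprainsim` simulates the first 0.30 s after foot–ground contact of a
single-limb drop landing, with the peak subtalar supination angle as the
primary outcome. The model is intentionally reduced: it keeps every
sprain-relevant causal pathway — impact energy, landing posture, surface
geometry, passive and brace stiffness, muscular protection — at a cost of
milliseconds per run, so that thousand-trial Monte Carlo studies and
repeated sensitivity probes are desk-scale.

Four generalised coordinates:

| coordinate | meaning | inertia |
|---|---|---|
| y | vertical position of the lumped body mass | 68 kg |
| z | lateral position of the same mass | 68 kg |
| θ₁ | talocrural rotation, dorsiflexion + | 0.012 kg m² |
| θ₂ | subtalar rotation, supination + | 0.008 kg m² |

plus a first-order muscle-activation state. The tibia is assumed to stay
vertical (no shank rotation); the ankle joint centre translates with
(y, z). The lateral degree of freedom is essential, not a luxury: with the
ankle pinned horizontally, any supination sweeps the sole medially —
uphill into a laterally dropping platform — and inversion is geometrically
locked for realistic foot widths at a 30° incline (|p_z| > |p_y|·tan i
would be required). The sprain mechanism is the body translating laterally
over the planted foot.

The rotational inertias are *effective* lumped values (shoe plus coupled
soft tissue), deliberately above bare-segment estimates; at segmental
values the 60 ms reflex latency exceeds the subtalar natural period and
the delayed feedback loop oscillates unphysically.

Joint axes: the talocrural axis defaults to pure mediolateral (0, 0, 1) in
a tibia frame with X anterior, Y superior, Z lateral (right limb); the
subtalar axis is built from its inclinations, 38° superior and 9° medial
to the anterior foot direction, giving the unit vector
(0.7783, 0.6157, −0.1233). Both axes are configurable. Positive rotation
about the subtalar axis combines inversion, adduction and plantarflexion —
supination.

## Contact

The platform surface passes through the origin with normal
n = (0, cos i, sin i): it drops on the *lateral* side, so the medial sole
border meets the ground first and the foot is forced to conform toward
inversion, the way inversion platforms work. Four sole points
(medial/lateral heel and forefoot, 9 cm below the ankle, ±4 cm lateral)
carry an elastic-foundation pressure law per point:

    f = max(0, A·E·δ·(1 + c·δ̇)),   δ = interpenetration

with per-point area A = 0.004 m², modulus E in MPa/m and dissipation c in
s/m taken from the per-trial inputs. The force is clamped non-negative
(never tensile). Tangential forces use regularised Coulomb friction,
−μ f v_t/√(|v_t|² + v_reg²), with μ = 0.9 (shoe on dry surface) and
v_reg = 0.05 m/s. Friction is required for the mechanism to exist at all:
a frictionless foot simply slides down the incline and the normal force's
medial component spins the foot without bound.

## Passive and brace bushings

Each rotational degree of freedom carries an uncoupled, rotation-only
restoring bushing with the double-exponential law

    τ_base(θ) = A(e^(−Bθ) − 1) − C(e^(Dθ) − 1),  θ in degrees,

with A = C = 0.227 N m and B = D = 0.10 /deg (odd-symmetric), which places
about 25 N m of restoring torque near 47° of supination — the scale at
which passive structures bear load in near-injury landings. Flexibility
rescales the *displacement* axis: τ(θ; flex%) = τ_base(θ·100/flex), so a
more flexible ankle reaches a given torque at proportionally larger
excursion. The brace duplicates this bushing in parallel with the
displacement axis divided by its scale: a 150 % brace reaches a given
torque at 2/3 of the baseline excursion (stiffer than anatomy), and scale
0 removes it. Scaling flexibility rather than torque reflects the view
that excursion at fixed torque is the quantity braces actually control.
A viscous term of 2.0 N m s/rad per joint (mid-range of reported passive
ankle damping) completes the bushing; below ~1.5 the protected
configurations show lightly damped oscillation that makes one-at-a-time
sensitivity probes sample noise rather than trend.

## Muscle controller

Only the subtalar axis is actuated (invertors/evertors; supination
positive, evertors act negatively). Two channels:

* **Neural channel** — a constant co-activation bias
  a·s·(τmax_inv − τmax_ev) (zero for the symmetric default
  τmax = 60 N m) plus a stretch reflex proportional to the supination
  excursion beyond the contact posture, sampled one latency (60 ms)
  earlier: τ_reflex = −gain·k_reflex·max(0, θ₂(t−λ) − θ₂₀). The summed
  command is bounded by strength-scaled maxima and drives a first-order
  activation state (τ_act = 40 ms), the standard excitation–contraction
  lag.
* **Intrinsic channel** — the short-range stiffness of the co-activated
  pair, −k_co·(θ₂ − θ₂₀) with
  k_co = a·s·½(τmax_ev + τmax_inv)·0.02 N m/deg per N m. This is a
  mechanical impedance, pre-engaged at contact: it is not a motor command
  and is not clipped by the neural cap. (Folding it inside the cap makes
  co-activation inert whenever the reflex saturates the evertors, which
  is both unphysiological and contrary to the consistently protective
  effect of co-activation.)

The reflex transduction constant defaults to k_reflex = 0.05 N m/deg per
unit gain, calibrated once against the reported deterministic behaviour
that even the strongest reflexes (gain 10) reduce the unprotected incline
sprain only marginally (here 46° → 42°): latency plus activation lag make
reflexes too late to prevent the sprain, while pre-engaged co-activation
is effective. At 1 N m/deg a gain-10 reflex would deliver hundreds of
newton-metres of demand and abolish the sprain outright.

Strength multiplies both channel amplitudes, so with co-activation and
reflex gain at zero the response is provably independent of strength.

## Integration and numerics

Fixed-step classical Runge–Kutta at dt = 0.1 ms over a 0.30 s
post-contact window, with the delayed reflex signal read from a
step-indexed history buffer and held constant within each step; output is
resampled at 2 kHz. Initial state: joints at the contact posture
(talocrural input is plantarflexion-positive and negated internally),
vertical speed −√(2gh), the foot lowered so the deepest sole point just
touches the surface, activation at the co-activation bias. The fixed-step
scheme was chosen over adaptive integration because the delay term makes
the system a DDE, and because it guarantees bit-identical trajectories for
identical inputs — a property the test suite asserts. A non-finite state
aborts with the last valid time. The core loop is numba-compiled (pure
IEEE scalar arithmetic, no fast-math), with a pure-Python fallback of
identical semantics.

Peak extraction takes the first sample attaining the maximum subtalar
angle; bushing moment vectors (τ₁·â₁ + τ₂·â₂ in the ground frame, per
bushing) are projected at that instant onto the anatomic axes and the JCS
triad; velocities are reported as signed largest-magnitude per-axis peaks
over the window.

JCS resolution uses the floating-axis sequence (dorsiflexion about the
tibia-fixed e1, inversion about the floating axis, internal rotation about
the calcaneus y-axis), implemented as an intrinsic Z–X′–Y″ decomposition
in a basis whose third axis is e1. e1 defaults to the talocrural axis
(mediolateral by default) and can be forced to pure mediolateral for
convention studies. |inversion| = 90° is a gimbal singularity and raises
an explicit error (tolerance 10⁻⁸ on the cosine).

## Probabilistic analysis

Inputs are independent; normals map from standard-normal space as
x = μ + σu and lognormals by moment matching
(σ_L² = ln(1 + (σ/μ)²), μ_L = ln μ − σ_L²/2). Zero-valued muscle/brace
table entries are treated as fixed-at-zero (a lognormal with mean 0 is
undefined). Percentiles use linear interpolation of order statistics
("type 7"). Failed trials are excluded with a logged count; more than 5 %
failures aborts. Probabilistic sensitivity factors are central finite
differences of the response mean and SD with respect to each input's mean
and SD (step 10 % of the input SD), every perturbed study re-using the
same standard-normal draws (common random numbers).

AMV: one evaluation at u = 0; forward-difference gradient with Δu = 0.1
(one evaluation per variable input); α = g/‖g‖; for each probability
level p one fresh evaluation at u\* = Φ⁻¹(p)·α, including p = 50 %
(no caching), so the cost is (p_var + 1) + n_levels evaluations — 14 for
ten variable inputs at three levels. For a linear response with normal
inputs the estimates are exact (μ_Y + Φ⁻¹(p)σ_Y), which the test suite
asserts to 10⁻⁶ relative.

## What the study designs emulate — and what passing tests show

The six built-in designs are the study conditions themselves: a fixed
incline (0° or 30°) with seven common input distributions (strength
100 ± 5 %, flexibility 100 ± 6 %, talocrural contact 34 ± 5°, subtalar
contact 0 ± 5°, drop height 0.30 ± 0.05 m lognormal, contact modulus
50 ± 5 MPa/m and dissipation 5 ± 1 s/m lognormal) plus study-specific
co-activation (60 ± 5 or 20 ± 5 %), reflex gain (10 ± 1 or 5 ± 1) and
brace scale (240 ± 6 or 150 ± 6 %). These distributions describe modest
uncertainty around one nominal subject and movement; they do not emulate
between-subject anthropometric variation, bilateral asymmetry, fatigue, or
correlated inputs. Passing tests therefore demonstrate internal
consistency and correct directions of effect under these conditions, not
predictive validity for any individual.

## Known limitations

* Single lumped mass: no knee/hip flexion absorbs the impact, so ground
  forces are higher and sharper than in vivo; the lateral slide that
  drives inversion is correspondingly longer (peaks often occur late in
  the 0.30 s window in protected configurations).
* The response surface is substantially nonlinear over ±2 SD of the
  contact posture: pronated-enough landings are caught by the muscles and
  never sprain (a cliff), while supinated landings saturate toward the
  geometric conforming angle (a ceiling). First-order AMV consequently
  reproduces the central percentile well but is biased in the tails
  relative to a large Monte Carlo — the known weakness of mean-value
  methods for non-monotone or strongly curved responses. The acceptance
  suite measures this comparison honestly rather than hiding it.
* Torque-level muscle model: no muscle paths, moment-arm geometry, or
  force–length/velocity properties; the co-activation stiffness and
  reflex transduction constants are lumped calibrations.
* Four contact points approximate a continuous sole; rolling over the
  lateral border is therefore slightly faceted.
* No injury threshold is asserted anywhere: outcomes are continuous peak
  mechanics, and the supination-for-inversion solver exists precisely so
  users can map them onto whatever external threshold convention they
  trust.
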