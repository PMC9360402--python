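# Methods

## The steering-circuit model

The model describes how a walking fly's central complex can convert an
odor-gated wind-direction signal into goal-directed locomotion.  All
directional variables are encoded as one-cycle sinusoidal activity bumps
across the fan-shaped body (FB), parameterised by FB location in degrees
(0 = left edge, 360 = right edge).  The circuit has three stages:

1. **Inputs.**  A heading bump `cos(fb − (180° − heading + shift)) + 1`
   enters each PFL output population with its anatomical phase shift (left
   PFL3 −90°, right PFL3 +90°, PFL2 180°).  A wind bump drives the 20
   hΔC local neurons; in the *allocentric* representation it follows the
   world-frame wind direction, while the *frontal* representation builds it
   from two heading-tuned PFN populations entering at ±45° whose
   amplitudes are scaled by `sin(wind_ego + 90° − peak)` with peaks at
   ∓45° egocentric.  Odor acts as a binary gain on the wind bump;
   optogenetic drive adds directly to hΔC activity.
2. **Local processing.**  hΔC output is phase-shifted 180° across the FB,
   projected from 20-neuron space to 8-column space through a
   row-normalised overlap matrix (each neuron's output footprint is one
   column wide), passed through a logistic nonlinearity
   (θ = 0.7, k = 0.1), and perturbed by an Ornstein–Uhlenbeck noise term
   (τ = 10 ms, stationary σ = 0.03).  An 8-neuron mutual-inhibition layer
   (opposite columns inhibit each other with weight 1.1; slow adaptation
   τ = 100 ms, weight 0.5) sharpens this signal; its 180°-shifted output
   is subtracted from the hΔC output to form the local drive to the PFL
   populations.
3. **Output.**  Each PFL population relaxes (τ = 1 ms) toward the logistic
   (θ = 1.7, k = 0.1) of its shifted heading bump plus the local drive.
   Angular velocity is proportional to ΣPFL3_right − ΣPFL3_left;
   groundspeed is `v_base + m2·ΣPFL2` (6 mm/s baseline, 0.25 mm/s per
   activity unit).  Poses integrate as `x += dt·v·sin(heading)`,
   `y += dt·v·cos(heading)`, so heading 0° walks upwind (+y).

A fly pointing away from the goal has its goal bump overlap the
constructively-shifted heading bump of one PFL3 side only; the resulting
left/right asymmetry turns the fly until the bumps align, at which point
the drive is symmetric and the heading is stable.  The stable heading
equals the allocentric wind direction, which is what makes odor-gated wind
bumps produce upwind walking from any initial heading.

## Numerical scheme and rate conventions

Behavior is sampled at `dt` = 50 ms.  The neural time constants (1 ms for
the inhibitory and PFL units) are far below `dt`, so the neural and
heading dynamics are advanced with `n_inner` = 50 exponential-Euler
substeps of `dt_inner` = 1 ms inside each behavioral step; exponential
updates (`u ← target + (u − target)·exp(−Δ/τ)`) are unconditionally
stable for any step-to-τ ratio.  The output noise uses the exact
one-step OU propagator, so its stationary standard deviation equals
`sigma_n` at any `dt`.  Within a step the order is: pose update with the
current heading and speed, noise update, stimulus assembly, the inner
loop (hΔC output → mutual inhibition → local output → PFL → heading
increment), the spontaneous-turn event, and the PFL2 speed readout, all
right-hand sides using previous-substep values.

The motor couplings are quoted at a 20 kHz reference sampling rate
(`rate_reference_hz`): the turn gain `m1` = 0.03 deg per reference step
per unit activity becomes 600 deg/s per activity unit, and the
spontaneous-turn rate λ = 3·10⁻⁴ per reference step becomes ≈6 events/s
(Bernoulli probability 0.3 per behavioral step).  Each turn event deflects
heading by a draw from N(0, σ_turn²) with σ_turn = 20°, treated as a
realised saccade angle.  These conversions were fixed by requiring the
closed-loop behaviors the model exists to produce — upwind convergence
within seconds and visible noise excursions — and are exposed in
`CircuitParams` for other readings.

**Mutual-inhibition threshold.**  `theta_mi` defaults to +0.15, which
keeps the inhibitory layer subthreshold (quiescent) at rest.  With the
opposite sign the layer is rest-active and its uniform state is linearly
unstable at every drive level (w·S′ ≈ 1.7 > 1 at the zero-input fixed
point), producing spontaneous rivalry oscillations that dominate baseline
turning (~70 deg/mm curvature with no stimulus) — incompatible with calm
pre-stimulus walking and with light-driven turning exceeding baseline.
The subthreshold default restores a calm rest state while preserving
drive-induced oscillations; the opposite sign remains settable.

## Simulated experiments

`ExperimentConfig`/`run_experiment` build cohorts of `n_flies × n_trials`
batched simulations with uniform-random initial headings per trial
(default pre 5 s, stimulus 10 s, post 10 s; no arena walls, positions
unbounded):

* **odor / frontal_odor** — odor gates the wind bump during the stimulus
  window;
* **sparse** — per fly, each of the 20 hΔC neurons is independently driven
  at 2.3 with probability 0.15 during the light window; the pattern is
  drawn once per fly from a fly-indexed seed stream and reused across
  trials.  All-zero draws (probability 0.85²⁰ ≈ 4%) are retained and
  flagged in the cohort manifest, mirroring stochastic-labeling
  variability;
* **broad** — uniform drive at 0.75 (low light) or 2.3 (high light);
* **ablation** — broad drive with the mutual-inhibition weights zeroed;
* **control** — hΔC output clamped to zero (empty-driver control), leaving
  only spontaneous-turn noise.

A single seeded generator drives the whole batch, so a master seed
reproduces a cohort bit-for-bit.

## Behavioral analysis

Tracks (50 Hz in the real assay; the simulator's 20 Hz output is handled
identically via the time column) are low-pass filtered at 2.5 Hz with a
zero-phase 2-pole Butterworth (orientation unwrapped with a 180° jump
threshold before filtering).  Kinematics are first differences over the
frame interval: groundspeed, upwind velocity (Δy rate), absolute angular
velocity of unwrapped orientation, and curvature = angular velocity /
groundspeed (deg/mm).  The first differenced sample of each trial is
undefined; samples below 1 mm/s groundspeed are excluded from all
time-averaged parameters; curvature is undefined at zero groundspeed.
Windowed means are compared to a 10–25 s baseline per fly.  Exclusions:
trials with < 25 mm path, flies with < 5 surviving trials; orientation
analyses further drop samples within 3 mm of declared arena walls and can
require ≥ 15 trials / ≥ 2000 retained samples per fly.  Simulated cohorts
declare no walls, so the wall filter does not apply to them.

**Orientation index.**  The orientation histogram (10° bins by default) is
drawn as a polar curve — one point per bin at radius equal to the bin
probability — and decomposed by SVD.  The index is the ratio of singular
values (≥ 1 by construction; isotropic ≈ 1, unimodal ≫ 1, degenerate
∞), and the preferred direction is the major-axis direction pointing into
the half-plane holding more histogram mass.  An alternative that applies
the same decomposition to centered unit-vector samples is provided for
comparison, but for unimodal data its major axis is transverse to the
mode, so the histogram form is the default.  Binning quantises the
preferred direction to roughly half a bin width.

Group statistics are nonparametric by default (two-sided Wilcoxon
signed-rank within fly, Mann–Whitney U between groups, Bonferroni
correction by the declared comparison count), with a t-test option for
upwind-orientation probability comparisons, and display-suppression rules
for small upwind increases (< 1 mm/s) and slowing-driven curvature
increases (angular velocity < 50 deg/s and groundspeed < 4 mm/s).

## Neural analysis

ΔF/F divides a fluorescence trace by the mean of its first 5 s excluding
the first sample (shutter lag); a (F−F0)/F0 variant is available.
Responsive columns exceed their baseline mean + 2 SD.  Direction tuning is
tested by one-way ANOVA across the five stimulus directions with trials
pooled over flies.

Decoding uses a classification tree (impurity-based, unlimited depth,
minimum leaf 1) on two predictors: fly identity (integer-coded
categorical) and the within-fly Z-scored response of the analysed phase.
Directions are pooled into left {−90°, −45°}, center {0°}, right
{+45°, +90°}; condition decoding (odor vs wind, odor vs baseline) pools
all directions.  Performance is the stratified 10-fold cross-validation
error, compared against 50 label-shuffled refits via a two-sided
permutation p-value `2·(1 + min(#shuffled ≤ obs, #shuffled ≥ obs)) / 51`
(minimum attainable 0.039).  Within-fly Z-scoring makes the decoder
exactly invariant to per-fly affine response scaling.

## Synthetic data generators

`gen_tracks` emulates the wind-tunnel assay's *windowed statistics*, not
its smooth kinematics: 70 s trials at 50 Hz, groundspeed 6 ± 0.5 mm/s,
baseline heading as a jump random walk (12 events/s, N(0, 90°) kicks —
deliberately fast decorrelation, τ ≈ 70 ms, so windowed means are stable
at 20-fly cohorts), an odor window (30–40 s) during which the fly
intermittently snaps into an upwind surge state (mean dwell 0.1 s,
heading spread 10°), and an optional post-odor window with multiplied
turn rate.  Surge occupancy is set to `q = drift / (v_base·E[cos h])`
with the Gaussian-surge expectation computed analytically, and wander
segments following a surge restart at a uniform heading, so the generated
mean upwind drift equals the requested value by construction.  Optional
arena bounds reflect positions.  Real fly headings are far more
persistent and speeds far more variable; passing recovery tests therefore
validates the estimators' calibration, not realism of the kinematics.

`gen_neural` emulates the five-direction wind/odor protocol: 5 blocks ×
5 directions per fly, von Mises direction tuning with a shared or
fly-specific preferred direction (κ = 0 for untuned), phase amplitudes
odor > wind = post-odor wind > baseline, per-fly lognormal response
scaling, and unit Gaussian noise.

## Verification sizes

The test suite and `scripts/acceptance.py` use: 120 runs (3 winds × 8
headings × 5 seeds) of 60 s for upwind convergence; 50 flies × 3 trials
for sparse reproducibility; 72 vs 72 flies × 5 trials (10–20 master
seeds) for the sparse-vs-control orientation-index comparison; 30 flies
per broad-activation condition; 20 flies × 30 trials per drift level for
recovery; 1000 null simulations at n = 20 for test calibration; 10⁵ steps
for the noise process; and 50 repeated decoder runs for the untuned
calibration.

## Known limitations

* The broad-activation curvature is **not** monotone in drive intensity
  here: the hΔC nonlinearity saturates both light levels (column drive
  0.62 at low vs 1.00 at high), and 0.62 sits at the mutual-inhibition
  layer's most oscillation-prone operating point while 1.00 is nearer
  saturation, so the *low* level produces the larger curvature (cohort
  means ≈ 62 vs 29 deg/mm over a ≈ 16 deg/mm baseline).  The oscillation
  window spans ≈ 1.7 activity units of drive, far wider than the 0.38
  separating the two levels, so no threshold placement can put low
  outside and high inside it.  Light-above-baseline and the
  ablation null are robust; only the high-vs-low ordering is not.
* No arena geometry: simulated cohorts have unbounded positions, so
  wall-related orientation biases cannot arise, and post-odor local
  search is absent from the circuit model.
* The integrator is a fixed-step scheme; accuracy at the default substep
  was verified against a 20 kHz forward-Euler reference for the
  mutual-inhibition layer, but very stiff parameter changes (τ ≪ 1 ms)
  should shrink `dt_inner` accordingly.
* The decoder reproduces the analysis contract, not any particular
  recorded dataset; with very narrow tuning (κ ≈ 8) and fly-specific
  preferred directions its unlimited-depth tree overfits and only
  marginally beats the shuffled null at realistic cohort sizes.
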