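# Methods

## Model

Two rate-coded populations are simulated explicitly: STATE cells (S) and
conjunctive STATE × ACT cells (SA).  Input populations (visual bearing
rings and the idiothetic ACT code) are imposed as functions of the agent's
true pose.  Every excitatory projection — VIS→S, SA→S, S→SA, ACT→SA — is
plastic; inhibition (lateral within each layer, plus a feedforward
visual-inhibition term gated by the lights flag χ) is fixed.

Activation of cell *i* sums gain-scaled, delay-shifted presynaptic rates;
the rate relaxes toward a logistic transfer of the activation with time
constant τ = 10 ms, threshold α = 2, slope β = 1, integrated by forward
Euler at dt = 2⁻¹⁰ s ≈ 0.98 ms.  Rates therefore remain in [0, 1] for any
input.  Within one timestep the order of operations is: delayed reads →
activations → Euler update → Hebbian update → row renormalization → push
rates into the delay buffers.  The Hebbian update uses the post-update
rates for the postsynaptic factor and the same delayed reads as the
activation for the presynaptic factor; with delays of 10–30 ms against a
~1 ms step, this one-step convention is immaterial, but it is fixed and
shared by the compiled kernel, the numpy path, and the test oracle.

Delays are rounded to whole timesteps (10 ms → 10 steps).  SA→S carries a
single 10 ms delay; S→SA delays are drawn per synapse uniformly from
[10, 30] ms.  VIS→S and ACT→SA are undelayed.  VIS→S and S→SA are 5%
Bernoulli-sparse (sparse connectivity prevents continuous-transformation
learning from collapsing the state code); SA→S and ACT→SA are full.
Plastic weights start uniform(0, 1) on the mask and are row-L2-normalized;
renormalization after every training step is per afferent projection
(a config flag selects the joint-across-projections variant), and rows
with norm < 1e−12 are left untouched so silent cells can be recruited
later.  The place model's FS and HD input subpopulations share one ACT→SA
projection whose columns carry their own gains (25.0 and 6.25), which is
algebraically identical to two separately scaled projections while keeping
one weight vector per SA cell for normalization.

## Environment and trajectories

The arena is a square navigable region |x|,|y| ≤ 10 (arbitrary units)
inside an outer barrier.  Distal landmarks are either ideal points at
infinity (study 1) or "ecological" points evenly spaced on the boundary
square of the outer region.  The outer halfwidth for the ecological
studies is 50: with distal cues at ±14 around a ±10 arena (a first
candidate), bearing parallax across the arena reaches ~60°, three times
the π/9 tuning width, and distal cues no longer behave as distal — the HD
model then fails to anchor to them.  At halfwidth 50 the residual parallax
is ~10°.

Proximal landmarks are scattered uniformly (seeded) within 35% of the
inner halfwidth — a central cluster the agent genuinely moves among.
This extent matters: landmarks scattered over 90% of the navigable region
are functionally distal (from across the arena a cue 15–25 units away has
slowly varying bearings), and the HD model then anchors to them, defeating
the proximal/distal dissociation the environments are meant to create.
With the central cluster, translation dominates the bearing dynamics of
proximal cues, which is what "proximal" means operationally here.

Training trajectories: study 1 pins the agent at the origin and resamples
the rotation state every 0.5 s uniformly from {none, cw, ccw}; studies 2–5
use a random walk that resamples every 0.25 s (rotate with p = 0.5 split
equally cw/ccw; move forward with p = 0.7), with angular speed π rad/s,
forward speed 1 unit/s, and heading redirected toward the arena interior
(with ±45° jitter) whenever a step would cross the inner barrier.  The
dwell times (≥ 0.25 s) are long relative to the 10–30 ms delays, which the
temporal-association learning requires.  There is no smooth acceleration:
action transitions are step functions by design.

Testing disables plasticity.  Rotation tuning records one full turn in
each direction at π rad/s (after a 0.5 s settling period), bins rates by
heading (360 bins; empty bins circularly interpolated) and averages the
two directions, cancelling the ~2° rate lag from τ.  The lattice test
visits an n×n Cartesian grid spanning 90% of the navigable region,
rotating fully in both directions at every point; place maps average over
headings per point, HD curves average over points per heading bin.  The
path-integration test rotates in place with the visual input (and its
feedforward inhibition) switched off halfway through.

## Analysis

HD selectivity: circular resultant length of the rate-weighted tuning
curve, preferred heading its argument.  A cell is HD-selective when the
resultant is ≥ 0.4, the curve peak is ≥ 0.1, and the half-peak lobe
containing the peak holds ≥ 75% of the suprathreshold rate mass
(unimodality).  Place selectivity: the field is the half-peak connected
component containing the peak; a cell is place-selective when
peak/mean ≥ 3, peak ≥ 0.02, field area ≤ 25% of the arena, and the field
holds ≥ 50% of the suprathreshold area.  All thresholds are configuration
fields reported alongside results; they are this package's
operationalization of informally used notions of "selective".  The rate
floors exist because amplitude-invariant statistics would otherwise count
near-silent cells; the place floor is set from the tuning width — a
conjunctive place × HD cell firing at rate 1 within one σ = π/9 band has a
heading-averaged map peak of at most ~0.056, so the floor must sit well
below that and above silent-cell speckle (~0.01).

Heading is decoded from STATE rates with a ridge-regularized linear model
on (sin θ, cos θ) targets, prediction via atan2 — ordinary linear
regression on a wrapped angle is ill-posed at the discontinuity, so the
literal linear-on-angle variant (Bayesian ridge) is retained only for
comparison.  The decoder is fitted on light-phase rotation and applied in
the dark.  The path-integration speed ratio divides least-squares slopes
of shortest-arc-unwrapped decoded and true heading over the dark window,
skipping the first 250 ms after lights-off (transient).

## Scaled presets

Full-size simulations (1000 STATE, 2000 SA, 3600 s of training at ~1 ms
steps) take hours on one CPU; scaled presets (200 STATE, 400 SA, 50 VIS
cells per landmark, 300 s of simulated training) exist for desk-scale work
and the test suite.  Naively keeping all full-scale gains
while shrinking layers 5× destroys the competitive regime: lateral
inhibition enters the activation as a raw population sum, so the active
*fraction* grows 5×, every cell wins for every stimulus, and the layer
saturates uniformly.  The scaled presets therefore rescale gains by
mean-field rules fixed in `config.scale_preset`: φ̄ × (population ratio) keeps
the active fraction invariant, and each projection gain × √(presynaptic
ratio) compensates the √N shrink of presynaptic rate-vector norms (the
3-cell AHV and 2-cell FS codes are not shrunk and keep their gains).
These rules were derived from the balance conditions, not fitted.

## What the generator does and does not emulate

The synthetic agent and environment implement the study conditions:
discrete action states, ideal noise-free Gaussian bearing codes, landmarks
never occluded, no acceleration, no sensory noise, and an idealized
ground-truth HD ring for the place model.  Passing tests therefore show
that the self-organization mechanism works under those idealized
conditions; they say nothing about robustness to occlusion, smoothly
varying velocities, noisy or remapping sensory codes, or learned (rather
than imposed) HD input — all outside this package's scope.

## Numerical choices

Double precision throughout the dynamics; recordings are stored float32.
The compiled kernel and the per-step numpy path share one arithmetic
contract (fixed summation order) and are cross-checked against a naive
scalar reference to 1e−12 over a thousand steps.  Euler stability demands
dt/τ < 1 and is validated at configuration time.  Ties between equally
near preferred angles are harmless (both cells receive equal rates).
Degenerate cases are defined explicitly: all-zero tuning curves score 0
and are not selective; zero rows are exempt from renormalization; the
speed ratio is undefined (raises) for zero true rotation.

## Known limitations

Scaled presets trade statistical power for speed: selectivity fractions at
200 cells have sampling noise of several percentage points, and shorter
training leaves the landmark-dependence contrast smaller than the
full-scale effect.  Two desk-scale limits are worth naming
explicitly.  First, residual conjunctive (place × heading) structure:
with 200 STATE cells the population cannot fully separate the spatial
manifolds, so a minority of HD-model cells retain place-criterion-passing
maps that a 1000-cell model washes out.  Second, dark-phase rotation
tracking: the asymmetric S↔SA connectivity that should rotate the
activity bump under an angular-velocity signal is demonstrably learned
(conjunctive cells affiliated with clockwise rotation project ~14°
clockwise-ahead of their input preferred heading, no-rotation cells
project symmetrically), and the bump is stable without self-motion, but
at desk scale the bump's cells sit tens of activation units above
threshold in the dark, and the small number of active conjunctive cells
delivers too quantized a push to unseat them — the decoded heading stays
pinned instead of tracking rotation at a substantial fraction of the true
speed.  Full-size dark-rotation tracking is therefore only expected from
the full presets (hours of CPU time).  The arena geometry and trajectory
statistics are package choices where the source conditions were
unspecified.  No spiking dynamics, no explicit inhibitory interneurons,
no occlusion, and no unified HD+place model (the place model's HD input
is ground truth).
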