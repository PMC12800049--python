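# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite shows.

## Task model

Each trial, one of two pathways is blocked by a guard.  Within a block
the blocked side is i.i.d. Bernoulli: P(block = biased side) = 0.88 in
biased blocks, 0.5 in control blocks.  A choice is *correct* iff it is
the open (unblocked) side.  Experiment 1 uses nine 20-trial blocks
(3 left-biased / 3 right-biased / 3 control) with the guard triggered
when the walker's forward position first reaches a per-trial uniform
draw from 0.8–1.2 m; experiment 2 drops one control block (3/3/2),
separates the pathways at 1.2 m, and triggers at 1.2–1.6 m, forcing a
binary early commitment.  Coordinates: x lateral (positive = right),
z forward from the start door; meters and seconds throughout.  The
within-biased-block counterbalancing is taken as i.i.d. draws, not an
exact-proportion shuffle.

## Benchmark actors

**Ideal actor.**  Beta posterior over P(left open), uniform prior
Beta(1, 1), reset at every block boundary (the regularity must be
re-inferred per block).  Each trial it chooses the side with the higher
posterior mean; exact ties — always trial 1 — are broken by a seeded
fair coin rather than a fixed side, to avoid systematic bias.  It then
observes the realized open side regardless of its own choice (walkers
always discover the open side) and increments the matching count.  Its
expected late-trial accuracy on a p-biased block is the realized
majority rate, ≈ p; simulated values at p = 0.88 are 0.88–0.89 over the
last five trials (trials 16–20, the convention used for all "late
trial" summaries).

**WSLS.**  Stay after a win, shift after a loss.  Both branches land on
the previously open side, so on i.i.d. sequences its stationary
accuracy has the closed form p² + (1 − p)² (0.7888 at p = 0.88) — the
analytic oracle used in the tests.

**Fixed policies** (always-left/right/majority-side) are analytic
checks on the generators; the majority policy's accuracy must match the
design bias within an exact binomial CI.

## Movement metrics

The primary measure is the lateral position at the last sample strictly
before the guard trigger (first sample with z ≥ trigger_z).  It is
sign-normalized so positive always points toward the *likely* open side
in biased blocks (flip iff right-biased) and toward the *actual* open
side in control blocks (a flag restores the unflipped variant, since
either reading of the control normalization is defensible).  Commitment
labels use a closed ±0.25 m threshold (the boundary counts as
committed).  Speed is the pre-trigger (x, z) arc length over elapsed
time — vertical gait oscillation is treated as noise and excluded.
Path length is the full-trial (x, z) arc length.  For z-grid
interpolation, walk-backs are handled by truncating each trial at its
first z-maximum (forward progress only); the untruncated series still
feeds path length.  The minimum-jerk reference maps the quintic
s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ from a trial's first to last (monotonized)
sample, and the deviation is the mean absolute lateral gap on a shared
50-point z-grid.

## Gaze metrics

I-DT in three dimensions: a greedy left-to-right window grows while its
dispersion stays within 5 cm; a grown window spanning ≥ 100 ms becomes a
fixation and scanning restarts after it, otherwise the start advances
one sample.  Dispersion is the maximum per-axis extent (a bounding box),
chosen over the classical Δx + Δy sum for 3-D symmetry; the sum variant
is available by flag.  Saccades are the complement: every maximal run of
non-fixation samples, including stream ends.  Non-finite samples
(blinks) split the stream; nothing is interpolated across gaps.  Only
samples before the guard onset are analysed.  Trial metrics: saccade
count / pre-guard duration, and the RMS distance of fixation centroids
from their common centroid (undefined with zero fixations; flagged).

## Statistical models

* **Lateral learning (experiment 1).**  Linear mixed model of the
  normalized last x on `expdecay = exp(−trial_in_block)` (indexed from
  1, so early trials carry large values), participant random intercept,
  optional random slope.  Fitting delegates to statsmodels `MixedLM`
  (REML); p-values use the normal approximation on z, matching the
  convention of reporting z-statistics for mixed models.
* **R².**  Marginal/conditional R² by variance decomposition:
  var(fixed predictor) / total and (fixed + random) / total, where the
  random-effect contribution averages zᵢ'Gzᵢ over observations and the
  residual is the model scale (π²/3 on the latent scale for the
  logistic model).  Standardized β = β·SD(x)/SD(y) on the estimation
  sample.
* **Binary learning (experiment 2).**  Random-intercept logistic GLMM
  fitted in-package by maximum likelihood with 25-node Gauss–Hermite
  quadrature (statsmodels offers no ML random-intercept logistic
  model); standard errors from the numerical Hessian; complete
  separation and vanishing random-effect variance are flagged, not
  hidden.  The saturating alternative a − b·exp(−c·t) is fitted to the
  same trial-level Bernoulli likelihood (L-BFGS-B, multi-start, bounds
  a ∈ (0, 1], b ∈ [0, 1], c ∈ (0, 5]) so the AICs are directly
  comparable; parameters pinned at a bound are flagged as unidentified.
* **Threshold trial.**  Smallest integer t with
  logit⁻¹(β₀ + β₁t) ≥ 0.80 from the fixed effects; "not reached" if the
  slope is non-positive or the block ends first.
* **Gaze models.**  Mixed models of saccade rate and fixation
  dispersion on trial-within-block, condition (biased vs control),
  block number, and the trial×condition and trial×block interactions.
* **Supporting tests.**  One-sample t, Welch t with pooled-SD Cohen's
  d, Kruskal–Wallis H, percentile bootstrap CI for a mean.

## Strategy clustering

Per-participant features from the last five trials of every biased
block, pooled across blocks (a per-block-mean variant exists by flag):
mean |last pre-guard x| and mean normalized last x.  k-means with
k = 4 on (|offset|, 2.0 × correct-offset), 25 seeded restarts,
best-objective selection; features stay in raw meters (the explicit
weighting presumes unstandardized inputs; a standardization flag
defaults off).  Cluster names come from centroid semantics, not index
order: the centroid nearest the origin is the Waiter, the largest
offset + alignment is the Super Learner, and of the remaining two the
lower correct-direction coordinate is the Random Walker.

## The synthetic generator

The generator reproduces the statistical structure the analyses assume,
not the physics of walking.  Agents hold a learning-rate-weighted Beta
posterior over the open side; the pre-trigger lateral profile is a
minimum-jerk shift of amplitude gain·(2·belief − 1) plus slow lateral
noise (white noise smoothed with a 1.5 s Gaussian kernel, rescaled to
the profile's marginal SD — postural sway is slow, so the jitter adds
negligible arc length).  After the trigger the path steers to the open
doorknob at ±1.5 m with a minimum-jerk blend, the noise tapering to
zero at the door.  Participants get an idiosyncratic lateral bias
(SD 0.05 m) and pace multiplier (SD 8 %), one RNG each, seeded from
(master seed, participant index) so any participant reproduces
independently; identical seeds give byte-identical CSVs.

Agent phenotypes mirror the four empirical clusters: waiters (zero
anticipation gain, 0.45 m/s), moderate learners (gain 0.18, discounted
evidence), a super learner (gain 0.6), and random walkers (random-sign
shifts).  The experiment-1 roster is 18/6/4/1 to match the empirical
cluster sizes; experiment 2 uses 23 learners choosing by posterior
(Thompson) sampling with a 6 % lapse — posterior sampling, unlike the
argmax ideal actor, yields the gradual logistic-shaped group curve
humans show — plus 2 random choosers, at base speed 0.57 m/s (the
measured pre-guard speed also includes the lateral commit swerve and
lands near 0.62 m/s).  The experiment-2 choice is the sign of x at the
1.2 m pathway separation; experiment-1 trials have no forced choice.
Gaze streams are planted fixations (Gamma-distributed durations) around
a far-door focus with linear saccade sweeps and 0.5 cm isotropic noise;
mean fixation duration grows across blocks and target spread shrinks
within and across blocks, mirroring the direction of the empirical gaze
adaptations.

What the generator does *not* emulate: biomechanics (balance, gait
dynamics, turning costs), reaction times, memory carry-over between
blocks, fatigue, or realistic eye-movement kinematics (main sequence,
smooth pursuit).  Tests passing on synthetic data therefore validate
the *pipeline* — detection, metrics, model recovery, clustering — not
claims about human behaviour.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make Monte-Carlo error
small relative to each assertion: 1,500–3,000 simulated blocks for
actor benchmarks; 100 replicates of the 29 × 6 × 20 design for slope
CI coverage; 500 null replicates at 20 participants × 4 blocks for
type-I calibration (calibration does not depend on the design size);
20 replicates of n = 5,000 trials for exponential-curve recovery, where
the per-replicate ML estimates of b and c scatter by ~25 % (the
likelihood is nearly flat along the b–c ridge) and the *mean* estimate
is the meaningful recovery check; 100 seeded eight-agent experiments
for the waiter-classification rate.  Exact-arithmetic checks (conjugate
updates, quintic boundary conditions, I-DT oracle equivalence) use no
tolerance beyond machine precision.

## Known limitations

* The logistic GLMM supports a single Gaussian random intercept; random
  slopes on the logit scale are not implemented (the linear models have
  them).
* Degenerate fits (singular random effects, separation, parameters at
  bounds) are flagged on the `ModelFit`, and it is the caller's job to
  act on the flags.
* The OSF column layout of the original recordings is not parsed; the
  pipeline consumes the package's own `trials/tracker/gaze` CSV schema.
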