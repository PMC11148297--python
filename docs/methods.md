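# Methods

## Task geometry and coordinate conventions

The goal (campfire) sits at the origin; distances are virtual metres (vm).
The avatar approaches the goal from (0, −10) at trial start.  The outbound
course leaves the goal along a 35.4 vm leg, turns through a 45° inner
angle, and continues 25 vm to the release point.  The frame is chosen so
the first leg points along −x and the triangle turns counter-clockwise;
with that convention the ideal home vector at the release point is
25.03 vm long (law of cosines) and deviates +89.93° (counter-clockwise)
from the continuation of the incoming heading — i.e. the ideal homing turn
is 90° to the nearest degree.  Directional estimates are signed angles
relative to the incoming heading on the second leg, positive
counter-clockwise, wrapped to [−π, π].  The turn angle is defined as
180° minus the interior angle at the release vertex; both are exposed.

The frame itself is a convention: only the leg lengths, the inner angle
and the 10 vm landmark radius are dictated by the task.  The default was
chosen so that the three goal-surrounding objects at polar angles
90°/210°/330° clear the walking corridor (minimum clearance ≈ 2.58 vm at
the default 2.5 vm corridor half-width); both the leg heading and the
object angles are configurable.

## Environments

Six nested conditions with 0/1/2/3/10/99 identical objects.  The first
three objects sit exactly 10 vm from the goal in a triangular arrangement
(angles configurable, see above) so that three objects fully triangulate
the goal.  Objects beyond the third are placed by seeded rejection
sampling, uniform in a 60 vm disc around the course centroid, with ≥ 3 vm
inter-object spacing and ≥ 2.5 vm clearance of the outbound and direct
return paths.  The full 99-object constellation is generated once per seed
and lower conditions take prefixes, so the nesting invariant (higher
conditions contain all objects of lower ones) holds by construction and
constellations are constant within a condition for a fixed seed.  The true
coordinates of objects beyond the first three in the original VR scene are
not published; the procedural layout is a stand-in that preserves the
stated constraints.

## The cue-combination model family

A goal estimate is treated as a distance estimate d and a direction
estimate x.  Distance information is a Gaussian ring density g(d) with
location μ_d and spread σ; direction information is a von Mises fan
density f(x) with location μ_x and concentration κ, normalised by
2π·I₀(κ).  All composition happens in log space with log-sum-exp guards.

* **Components.**  The PI system contributes one ring and the single fan,
  both anchored at the release point.  Each object contributes one ring
  fixed at μ_d = 10 vm with a shared spread σ_LM taken from the spread of
  distance estimates to the single object in the one-object condition
  (`estimate_landmark_sigma`), or supplied explicitly.  Only the four PI
  parameters are ever fitted, keeping all variants in the same model class.
* **Composition.**  Landmark rings combine multiplicatively (integration,
  Σ of logs) or as an equal-weight mixture (alternation).  The plain sum of
  densities is not a density, so the alternation combination is divided by
  the number of rings; weights can be overridden.  The combined distance
  term is always multiplied with the fan: L = f(x)·g_combined(d).
* **Fitting.**  μ_d and σ are the Gaussian MLEs of the radial distances
  (1/n denominator, so the closed-form fit maximises ℓ); μ_x is the
  circular mean.  κ defaults to the reciprocal-of-circular-SD rule
  (κ = 1/std(x)); the standard Bessel-ratio MLE (invert I₁/I₀ at the mean
  resultant length) is available as `kappa_estimator="mle"` and is the
  estimator used in parameter-recovery checks, because the reciprocal rule
  is a coarse approximation (for a true κ = 6 it returns ≈ 2.3).  Location
  parameters are fitted as (circular) means rather than the medians named
  alongside the densities' definitions; for the symmetric densities in the
  family the two coincide in expectation.
* **Likelihoods and comparison.**  ℓ = Σ log L, with AIC = 2k − 2ℓ and
  BIC = k·ln n − 2ℓ at k = 4 free parameters.  L as written is not a
  normalised density over the plane: the product of K landmark rings
  carries an implicit normaliser far below 1, which penalises integration
  variants in raw-ℓ comparisons regardless of fit (the fan and PI-ring
  factors are shared and cancel).  `combined_loglik` therefore keeps the
  raw convention by default but accepts `normalize=True`, which divides by
  the grid-integrated mass of the model surface; `compare_models`
  normalises by default so that integration and alternation variants are
  compared on proper densities.  With normalisation, model-type recovery
  on synthetic data is clean in both directions (≥ 90% required, 100%
  observed at 200 trials × 100 replicates).  No polar-area Jacobian is
  applied when evaluating f(x)·g(d) at an endpoint — d and x are treated
  as independent 1-D estimates; the grid normalisation operates on the
  resulting plane score.
* **Uncertainty.**  Percentile bootstrap CIs for all PI parameters from
  nonparametric trial resamples (B ≥ 100; degenerate all-identical
  resamples are skipped and counted).  Nominal 95% CIs for μ_d cover the
  generating value ≈ 94% of the time at n = 400 trials.
* **Surfaces.**  `evaluate_surface` grids exp(log L) over a bounding box
  covering every ring's annulus (default resolution 0.25 vm) and
  normalises to sum 1; the argmax cell is exposed.  For the full
  three-object integration model the argmax falls within 1 vm of the goal.

## Synthetic data

All generative noise is injected at the endpoint-report level; no claim is
made about whether it originates in perception, memory or motor control —
the PI system is treated as noisy as a whole.

* **PI-only**: d ~ Normal(μ_d, σ) truncated at 0 by resampling (negligible
  for μ/σ ≥ 5), x ~ von Mises(μ_x, κ), mapped to the plane from the
  release point.  This sampler is exact.
* **Integration**: endpoints sampled from the normalised product surface
  on a 0.25 vm grid (cell probabilities at cell centers, uniform jitter
  within the cell).  With no landmark rings the generator reduces exactly
  to the PI-only sampler.
* **Alternation**: one object per trial is drawn by weight (equal by
  default, mirroring the random mis-identification account of clutter
  confusion), and the endpoint is sampled from that object's normalised
  f·g component.  As mixtures spread mass, alternation endpoint SD is
  never below the integration SD with the same components; integration SD
  is below the PI-only SD (variance reduction through cue combination).
* **Study composer** (`simulate_study`): balanced trials per participant ×
  condition × session.  Condition 0 is PI-only; conditions 1–3 integrate
  PI with all present landmark rings; in the 10- and 99-object conditions
  each trial is alternation-generated over *all* objects with the
  participant's `clutter_confusion_prob`, otherwise integration-generated
  with the three goal-surrounding rings.  The confusion probability is a
  synthetic knob — it has no measured counterpart — introduced to
  reproduce the qualitative split between participants who do and do not
  degrade in clutter.  One child seed per participant × condition is
  spawned from a single root seed, so tables are bit-reproducible.

`default_cohort` encodes the study-scale population: 23 participants;
distance bias ~ N(+1.5, 1.5) vm and direction bias ~ N(+8°, 8°)
(population-level overshoot of both the return distance and the 90° turn);
distance noise ~ N(4, 1) vm clipped at 1.5; direction noise ~ N(26°, 8°)
clipped at 8° (a ~26° directional spread in the PI-only condition);
roughly half the cohort (11/23 in expectation) draws a high confusion
probability (0.6–0.9), the rest near zero.  The generative concentration
uses κ = 1/sd² so sampled angular spread matches the profile's direction
SD.  Landmark ring spread defaults to 2 vm.  With these defaults the
simulated cohort shows the intended qualitative pattern: median error
~10 vm with no objects, ~2 vm with three, and a precision collapse in
clutter carried by the confused subgroup.

What the generators deliberately do not emulate: trajectories, timing and
timeouts, session-order learning effects, emergent configuration cues in
clutter, and any systematic (non-random) tree mis-identification.  Passing
tests therefore validate the estimators and model comparison under the
stated generative assumptions, not the full richness of real behaviour.

## Metrics and classification

Accuracy is the median position error per participant × condition;
precision is the SD of position error with the n−1 denominator.  Clutter
deltas are raw-scale differences (no log transform): condition 0 minus 3
(low clutter) and 3 minus 99 (high clutter), for both measures.  Two
grouping procedures are reported side by side, as they answer slightly
different questions and need not agree: (1) participants whose
high-clutter delta falls outside the bootstrapped 95% CI of the cohort's
median delta, and (2) a per-participant two-sample Wilcoxon rank-sum test
on single-trial errors between the 3- and 99-object conditions (exact null
distribution below n = 20 without ties, tie-corrected normal approximation
otherwise; delegated to `scipy.stats.mannwhitneyu`).  Under the null the
rank-sum classification labels ≤ 7% of participants as changed at
α = 0.05 (measured ≈ 5%).  Kernel-density summaries of delta
distributions (Gaussian kernel, Silverman bandwidth) and the Shapiro–Wilk
normality check are reporting utilities; no inference hangs on them.

The exclusion filter removes trials with missing endpoints, truncates to
the first four main sessions for balance, and can drop participants
missing a condition; every rule's count is reported.

## Regression stage and power analysis

The condition-effect regressions model the log of the zero-bounded error
measures with condition as an ordinal factor; forward-difference contrasts
make each coefficient an adjacent-level mean difference so effect
reversals show up as sign changes.  The mixed-model fitting is delegated
to statsmodels (`MixedLM`, fitted by ML so the likelihood-ratio test
against the fixed-effects-only model is well defined); this module owns
only transforms, codings, comparisons and reporting.  The variance
component null lies on the parameter boundary, so the plain χ²(1)
reference for the LRT is conservative — acceptable here because the test
is used as a forward check, not a calibrated error rate.  The
low/high-clutter split is supported by a quadratic regression over the
ordinal levels: the vertex −b/(2a) is reported with a sign check (a > 0
for a minimum) and a nested F-comparison against the linear fit; on noisy
U-shaped data with a generating minimum at level 3 the vertex is recovered
within ±0.5 levels in ≥ 90% of replicates.

The minimal detectable difference of a one-sample t-test is computed via
the noncentral t distribution (both rejection tails counted when
two-sided) and root-finding in the true shift δ to 1e-6 vm.  The target
power is read as 1−β = 0.95.  At the pilot within-participant SD of
2.78 vm and n = 24 the MDE is 2.137 vm; at the between-participant SD of
4.02 vm and N = 20 it is 3.419 vm.

## Numerical choices and edge cases

* Grid resolution defaults to 0.25 vm for surfaces, sampling and
  normalisation (0.5 vm in the pipeline for speed); grid sampling is
  piecewise-constant at that resolution.
* κ = 0 is the explicit uniform direction limit; endpoints at the fan
  vertex have no defined angle and are excluded with a warning.
* A fitted σ at rounding-noise level (≤ 1e-12·max(1, μ_d)) flags the fit
  as degenerate rather than producing infinite likelihoods.
* The von Mises density approaches Normal(μ, 1/√κ) at large κ with
  O(1/κ) peak discrepancy (~5e-3 at κ = 100); tests assert agreement at
  that scale.
* Bootstrap and percentile procedures are deterministic per seed; the
  pipeline derives every stage's seed from the config, and outputs carry a
  provenance header (config digest, seed, package version).

## Problem sizes

Tests and the acceptance script run at study-like but economical sizes:
parameter recovery at 2,000 trials; model-type recovery at 100 replicates
of 200 trials per direction; variance ordering at 5,000 samples per
generator; bootstrap coverage at 200 replicates (n = 400, B = 200);
classification error control at 1,000 null participants with 24 trials per
condition; quadratic-minimum recovery at 200 replicates of a 23 × 6
design.

## Known limitations

* Raw (unnormalised) ℓ comparisons across composition modes are reported
  for fidelity but are not size-consistent across modes; use the default
  normalised comparison for model selection.
* The reciprocal κ rule is biased at moderate concentrations; prefer the
  Bessel-ratio MLE when the value of κ itself matters.
* The alternation model treats every object as an equally likely "correct
  tree"; it cannot express systematic confusion patterns or configuration
  learning.
* The loader expects the package's own CSV schema; mapping a deposited
  experimental dataset onto it requires a column mapping by the user and
  has not been validated against a live archive.
* Real-data quantities (regression coefficient tables, empirical medians,
  the exact participant split) depend on the deposited dataset and are
  emulated only qualitatively by the synthetic cohort.
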