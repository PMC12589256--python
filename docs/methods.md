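# Methods

## Task and models

Temporal generalization: on each trial a probe duration *t* is presented and
the observer reports whether it matches a learned standard *S* (0.4 s in the
reference designs). The data are binary same/different responses, so a model
is fully specified by its psychometric function P("same" | t), and the
trial-level likelihood is Bernoulli.

All four models are two-boundary readout rules on a noisy decision variable:

* **ddm** — the decision variable at probe offset is the state of a
  drift-diffusion process, normal with mean *t* and SD *c*·√*t*. Drift is
  normalized out: `b_l`, `b_u` (seconds) are boundary-to-drift ratios and
  `c` (s^0.5) the diffusion-to-drift ratio. An explicit-drift
  parameterization would be observationally equivalent and is not exposed.
* **bsu** — identical boundary logic with linear noise, SD = *k*·*t*. The
  four-parameter variant with an additive bias term is deliberately not
  implemented: the bias trades off perfectly with the boundaries when only
  generalization data are available, so the three-parameter form is the
  identifiable one.
* **cg / mcg** — symmetric boundaries at (1 ± *B*) around the standard with
  trial-to-trial boundary variability σ_B, plus Weber-scaled variability *k*
  in the remembered standard. In `cg` the noisy memory sample itself
  normalizes the decision variable (hence the two z-scores have different
  denominators and the gradient is asymmetric); `mcg` replaces it with the
  objective standard in the denominator.

Model functions are pure and unclamped. The positivity constraints used in
fitting (below) are not imposed on evaluation: `CGParams` accepts the
degenerate σ_B = 0 or k = 0 closed forms (not both zero), which serve as
algebraic checks.

## Fitting

The log-likelihood sums `r·log p + (1−r)·log(1−p)` over trials with *p*
clamped to [1e-12, 1−1e-12]; the clamp lives only in the likelihood, keeping
model functions exact while preventing −∞ under perfect (mis)prediction.
Because *p* depends on the data only through the design's durations, the
likelihood is computed on per-duration response counts, making fit cost
independent of trial count.

Optimization is Nelder–Mead from 8 starting points (every combination of two
values per parameter): cg/mcg start at B ∈ {0.1, 0.5}, k ∈ {0.05, 0.5},
σ_B ∈ {0.05, 0.5}; ddm/bsu at b_l ∈ {1.25·min duration, mean duration},
b_u ∈ {0.75·max duration, mean duration}, and noise ∈ {0.05, 0.5} (ddm) or
{0.1, 0.5} (bsu). The "mean duration" is the unweighted mean of the unique
probe durations (3/7 s for the reference design). Convergence tolerances are
1e-6 on both simplex size and function value, at most 2,000 iterations per
start; ties between equally good starts resolve to the lowest start index.

Constraints are enforced by the search parameterization rather than by a
constrained optimizer: cg/mcg optimize (log B, log σ_B, log k), which keeps
all three parameters strictly positive (equivalent in effect, not in
algorithm, to a box-constrained search), and ddm/bsu optimize
(log b_l, log(b_u − b_l), log noise) so the boundary ordering b_u > b_l can
never be violated. A start with coincident boundaries gets its separation
floored at 1e-3 s. B > 1 (lower boundary at negative durations) is allowed
and left to the analyst to flag.

Shared-parameter fits across conditions (used for AIC-based model
comparison of "did this parameter change?") maximize the joint likelihood
over 1 shared + 2·n_conditions free parameters. Here each coordinate must be
a single named parameter, so the search runs in log-natural space with a
penalty wall for b_u ≤ b_l, warm-started from the unconstrained
per-condition fits. Free-parameter count is 2·n_conditions + 1 per
participant; AIC = 2k − 2·log L.

A fit failure (no start with a finite likelihood) yields an explicit failed
`FitResult` rather than an exception, and winner tables drop such
participants with a warning.

## Synthetic data and recovery campaigns

`simulate_trials` draws independent Bernoulli responses from the model curve
at the design's per-duration trial counts. The reference designs are: 225
trials (45 standard = 20%, 30 per other probe), its threefold version (675),
and the learning-experiment variants (80-trial blocks, 25% standard). All
randomness flows through explicit seeds; campaigns fan out per-simulation
seeds with `SeedSequence.spawn`, so results are reproducible bit-for-bit and
independent of execution order.

Cohort parameter distributions are gamma for boundaries (and bsu's k) and
exponential for cg/mcg's σ_B and k — exponential because fitted noise
parameters of those models pile up near zero. Distribution fitting applies a
3×IQR-from-the-median outlier rule vector-wise before estimation; gamma
parameters are maximum likelihood with location fixed at zero (moment
matching as fallback for degenerate samples), exponential means are sample
means. Parameter sampling redraws the whole vector until b_u − b_l ≥ 0.1 s
(capped at 10,000 attempts), which keeps simulated observers out of the
near-collapsed regime; the truncation induces a small positive correlation
between sampled boundaries, which should be remembered when interpreting
estimated boundary correlations.

The shipped default distributions for `ddm` are moment-matched to empirical
auditory-modality estimates (b_l 0.27 ± 0.06 s, b_u 0.54 ± 0.09 s,
c 0.17 ± 0.06). The `bsu` and `cg`/`mcg` defaults are synthetic,
field-plausible choices in the same families (bsu boundaries somewhat wider
and noisier than ddm's, cg/mcg noise means 0.1 and 0.3); they are stand-ins,
not estimates, and campaign statistics driven by them (hit rates,
correlations) characterize this package's defaults rather than any
particular dataset. Consequently only orderings and monotonic relations are
asserted about model-recovery hit rates, never specific percentages.

Parameter recovery excludes a simulation when any estimated parameter
exceeds 5× the largest *simulated* value of that parameter in the campaign,
then reports Pearson correlations, estimated-on-simulated regression lines,
and the cross-parameter correlation matrix on the kept set. Model recovery
fits all four models to each simulated dataset and scores the winner by
maximum log-likelihood — with all models at three parameters this equals
minimum AIC. The bootstrap correlation null resamples kept simulations with
replacement at the empirical cohort size and reports the fraction of null
correlations at least as large as the observed one.

What the generator does *not* emulate: response times, serial dependence
between trials, lapses/attention drifts, and learning within a session.
Passing recovery tests therefore show identifiability under ideal
stationary Bernoulli responding, not robustness to those violations.

## Optimality analysis

Expected accuracy of a ddm observer on a design is
Σ_t P(t)·[t = S ? P(same|t) : 1 − P(same|t)]. For count-specified designs
the sum is computed with exact integer weights (`dot(counts, ·)/N`), so
degenerate strategies evaluate exactly (always-"different" under a 20%
standard gives exactly 0.8). Boundary search runs Nelder–Mead in
(log b_l, log separation) from a symmetric-around-S start plus, along a
noise grid, a warm start from the previous solution.

When the standard is rare, high noise makes the always-"different" strategy
optimal; any coincident boundaries implement it, so collapsed solutions are
canonicalized to b_l = b_u = S with a flag. Collapse is detected when the
optimal separation falls below 1e-4 s or the achieved accuracy is within
1e-6 of 1 − P(standard). With exact 225-trial design probabilities (0.2 and
2/15) the exact optimum stays marginally above 0.8 until c ≈ 0.178 — the
excess is below 1e-3 from c ≈ 0.173 — so the practically relevant collapse
region is the 0.15–0.18 band; under P(standard) = 0.5 no collapse occurs
and the optimal separation widens with noise. The default grid spans
c ∈ [0.001, 0.6] (zero noise excluded: its optimum is non-unique), a choice
covering the empirically typical range.

## Participant screening

Flat responders (judgments unrelated to the probe duration) are flagged by a
likelihood-ratio test: a one-parameter constant-probability model against
the best of the four three-parameter models, χ² with 2 df. A participant is
excluded when the constant model is *not* rejected at α (default 0.01);
α = 0 disables the screen. This is a principled stand-in for what is
usually done by eye, and is off by default in the CLI `fit` command.

## Problem sizes and tests

The test suite exercises campaigns at 100–200 simulations and recovery
designs up to 675 trials; these sizes give stable orderings (binomial SEs of
a few percentage points on hit rates) while keeping the default suite quick.
Large-scale claims (e.g. 5,000-simulation campaigns) scale linearly from the
same code paths via the CLI flags.

## Known limitations

* No response-time modeling: the ddm here reads the accumulator at probe
  offset and ignores first-passage dynamics, so it predicts choices only.
* cg/mcg noise parameters are not jointly identifiable at typical trial
  counts; the recovery tools quantify, rather than fix, this.
* Upper boundaries near or beyond the longest probe are weakly constrained
  by the design and tend to be overestimated; treat large fitted b_u with
  caution.
* No hierarchical/Bayesian estimation and no parameter standard errors.
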