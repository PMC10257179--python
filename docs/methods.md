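# Methods

## Outcome and data model

The unit of analysis is one rat pup's brain-area-loss percentage: 100 × (1 −
Σ ipsilateral area / Σ contralateral area) over the measured sections,
clipped below at 0 for the oedema case where the injured hemisphere measures
larger. Section areas are summed before the ratio is taken, so larger
sections carry proportionally more weight; averaging per-section ratios
instead would differ only when neighbouring sections differ substantially in
size, and the summing convention keeps the statistic a property of total
tissue. Outcomes live in [0, 100] by construction.

Records carry experiment, litter, treatment and sex labels. Every experiment
must contain a control ("HI/saline") arm; the loader normalises common
control aliases and rejects rows violating the range or uniqueness
invariants with row-numbered diagnostics.

## Quality gate

An experiment is analysable only if its injury severity is moderate: the
control-arm median loss must lie in the closed interval [35, 50] percent.
"Between 35 and 50" is read as closed — the exclusion rule is stated as
`< 35` or `> 50`, so the boundary values are retained. Excluded experiments
are removed with all their arms; the gate is idempotent and never modifies a
retained record.

## Hierarchical model and priors

y_ij = μ + α_i + Σ_k β_k·1{Trt=k} + ε_ij with α_i ~ N(0, τ²), ε_ij ~
N(0, σ²), reference coding β_control ≡ 0. A treatment appearing in several
experiments shares one β. Locations (μ, β) take improper flat priors. For
the scales the default is a flat prior on the SD (p(σ) ∝ 1, p(τ) ∝ 1),
which gives conditionally inverse-gamma updates and a proper posterior for
the ~20-experiment regime this package targets; with very few experiments a
flat prior on τ is risky, so a half-Cauchy(scale = 10 points) alternative is
available and sampled exactly through the inverse-gamma mixture
representation.

## Sampler

Blocked Gibbs: (μ, β) jointly from their Normal full conditional (a single
Cholesky solve of XᵀX, precomputed), each α_i from its Normal full
conditional, σ² and τ² from inverse-gamma conditionals. Initialisation uses
moment estimates (control grand mean, group-mean differences, pooled SDs)
with overdispersed per-chain jitter scaled to the data SD. Chains are
seeded from independent substreams of one master seed, so runs are
bit-reproducible. The default protocol is 4 chains × 10,000 iterations,
first 5,000 discarded, no thinning — 20,000 retained draws. Variance draws
are floored at 1e-12 to avoid a degenerate zero state on pathological
(zero-residual) inputs.

Two fixed-parameter modes exist for verification rather than analysis:
`fixed_sigma` (known residual SD) makes the (μ, β) posterior exactly Normal,
giving a closed-form oracle the sampler is tested against; `fixed_tau = 0`
switches the random effect off, collapsing the posterior means onto OLS.

The concurrent-control analysis refits the same model to a single
experiment with the random effect removed (α is unidentifiable from one
experiment); whether the original analysis derived its concurrent estimates
this way or from pooled-model contrasts is not documented, and the
single-experiment fit was chosen as the more literal reading of
"vs. concurrent control".

Convergence is monitored with split R-hat and rank-normalised bulk ESS
(ArviZ); parameters with R-hat > 1.01 or ESS < 400 are flagged, not
silently accepted.

## Efficacy summaries

Posterior median and 95% credible interval use sample 2.5/50/97.5
percentiles with linear interpolation between order statistics (numpy's
default convention, recorded here as the package's convention).
Pr(efficacy) is the strict fraction of draws below zero; draws exactly zero
count as non-efficacious. The ranked table sorts by pooled Pr(efficacy)
descending and marks a treatment significant when its 95% interval excludes
zero. No multiplicity adjustment is applied across arms — deliberately, to
match the screening design where each candidate is judged on its own
posterior; users comparing many arms should treat the ranking as a screen,
not confirmatory inference.

Per-experiment comparisons use the two-sided Mann–Whitney rank-sum test
with midranks: full enumeration of all C(n, n₁) allocations for combined
n ≤ 20 (counting |W − E[W]| at least as extreme as observed), otherwise the
Normal approximation with tie and continuity corrections. The test identity
behind the published per-experiment p-values is not documented; Mann–Whitney
was chosen as the test consistent with median-and-range reporting of a
bounded, skewed outcome, with a Welch t-test behind a flag for sensitivity.

## Outlier-litter exclusion

Runs on control animals, grouped by litter within experiment (the grouping
key is an argument: grouping by experiment is also meaningful when litters
map 1:1 to experiments). Loop:

1. Kruskal–Wallis across litters (midranks, tie-corrected H, chi-square
   p-value with K−1 df). Stop if p > 0.05.
2. Deviant litter j = the one maximising |R̄_i − (n+1)/2|. The absolute
   deviation is used because the procedure targets abnormally small *or*
   large litters; the literal one-sided argmax (high litters only) is
   available via `one_sided=True`. Ties break toward the larger litter,
   then the lexicographically smallest label. The contrast c_j = −1,
   c_i = 1/(K−1) gives T = (Σ c_i R̄_i / SE)² with
   SE = √(n(n+1)/12 · Σ c_i²/n_i). For K = 2, T reduces algebraically to H.
3. Permutation p-value: observations are reshuffled over the fixed litter
   sizes (equivalently, the fixed midrank vector is permuted — the ranks of
   the pooled sample do not change under shuffling, which is what makes the
   fully vectorised implementation exact). Within each permutation the
   deviant litter is re-selected before T is computed, so the null
   distribution accounts for the data-driven selection; freezing the
   observed j is available via `reselect=False`. p = strict fraction of
   permuted T exceeding the observed T; default 10,000 random permutations,
   with exhaustive enumeration of all distinct assignments below a
   configurable cap.
4. If p ≤ 0.05 the litter is excluded (all its animals, every arm) and the
   loop restarts on the survivors; K = 1 forces a stop.

Degenerate saturation — every permuted T tying the observed T, which would
force p = 0 under the strict inequality — stops the loop with a flag
instead of excluding: a tie-saturated permutation distribution carries no
evidence. The tie fraction between permuted and observed T is reported
whenever it exceeds zero so heavy-tie instances are visible.

## Synthetic trials

The generator samples the hierarchical model in its forward direction with
the trial's structure: defaults of 20 experiments; control and treated arms
of 7–14 pups; litters of 8–15, filled after randomising pups so arms share
litters; sexes alternating; μ = 41.46% (the pooled control median of the
screening trial); τ = 5 points; σ = 12 points. σ was chosen so that the
simulated control range matches the observed 0–65% spread, and τ so that
experiment-level control medians scatter several points around μ; both are
defaults, not claims about the real data. `study_like_config` adds 25
candidate treatments with effects evenly spanning −26 to +9 points (the
span of the reported effect estimates), one experiment per compound, the
first five experiments carrying two arms. An optional litter-level random
effect (default SD 0) supports sensitivity studies of the exclusion
procedure, which implicitly targets such effects.

Outcomes are Gaussian but the outcome scale is a percentage; generated
values are clipped to [0, 100] with the clip count recorded in provenance
(well under 0.1% of animals at the default parameters).
`generate_unclipped` returns the raw Gaussian outcomes for model-exact
checks. RNG substreams are spawned per experiment, so extending a trial
never perturbs existing experiments.

What the generator does not emulate: mortality and dropout, weight and
temperature covariates, sex effects, non-Gaussian residuals (the real
outcome is bounded and left-skewed near the floor), and litter effects
unless requested. Passing tests therefore demonstrate correctness of the
machinery under the stated model, not robustness to every feature of real
histology data.

## Problem sizes used in verification

The parameter-recovery study runs 50 replicates of a 20-experiment trial
(groups of 10; μ = 41, τ = 5, σ = 12; β = −20/−10/0) with 4 × 2,500-draw
chains, checking 95%-interval coverage ≥ 90% and mean posterior-median bias
within ±1.5 points per β. Exclusion operating characteristics use 1,000
null replicates (5 litters × 10) and 200 shifted-litter replicates at 2,000
permutations each. The full 4 × 10,000 protocol is exercised by the
acceptance script's pipeline run and asserted on the default configuration.

## Known limitations

- The Gaussian likelihood ignores the outcome's floor at 0; with severe
  effects (near-total protection) posterior intervals can cross below 0
  loss, where the model is a convenient approximation.
- Flat-on-SD priors with very few experiments (I ≲ 3) make τ's posterior
  heavy-tailed; prefer the half-Cauchy prior there.
- The permutation p-value's resolution is 1/N; exclusion decisions near
  α = 0.05 can flip between seeds at small N.
- Exhaustive permutation enumeration is factorial; the capacity guard
  redirects large instances to random mode.
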