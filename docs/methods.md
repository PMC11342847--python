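# Methods

## Task environment

The synthetic task mirrors a card-deck magnitude-learning design. Card
values are the integers 1–13 (ace to king, global mean 7). Deck
distributions are pmfs on that support with exact means 8 (high) or 6 (low):

* **narrow** — discretized Gaussian, sd 1.0;
* **broad** — discretized Gaussian, sd 2.5;
* **bimodal** — two-component mixture of discretized Gaussians (sd 1.0)
  with modes near 3 and 12, component weights fixing the mixture mean.

Unimodal decks are restricted to a symmetric support of mean ± 5 cards
(3–13 for high, 1–11 for low). This makes them exactly symmetric: the task
manipulates variance at fixed mean, and an asymmetric truncation would
otherwise add skew that contaminates same-mean comparisons (a long lower
tail on the broad-high deck, a long upper tail on broad-low). After
discretization every pmf is exponentially tilted (`p_i ∝ p_i e^{λx_i}`, λ
solved by root finding) so the mean is exact to < 1e-12; for the symmetric
decks λ = 0. Realized variances: narrow 1.00, broad 5.26, bimodal ≈ 19–21.
All pmfs can be overridden per deck through the task config; overrides are
validated against the mean/variance invariants.

Blocks draw outcomes i.i.d. per deck. Feedback is full — both cards are
shown each trial — so learning never depends on the agent's own choice; the
choice only determines the signed points (chosen minus unchosen card).
Option "a" is defined as the higher-mean deck, or the broader deck when
means are equal, so a-choice rates read directly as accuracy or
broader-option preference.

## Models

Outcomes enter the models rescaled linearly to [0.01, 0.99] (card 1 → 0.01,
13 → 0.99, 7 → 0.5). All models share the softmax choice stage
P(a) = 1/(1 + e^{−β(V_a − V_b)}) and initialize expectations at 0.5.

**1lr-RW.** V ← V + α(R − V). Parameters α (learning rate) and β (inverse
temperature).

**2lr-RW.** As above with α₊ applied when the prediction error δ ≥ 0 and α₋
when δ < 0 (ties take the positive branch). The positive learning bias
α₊/(α₊+α₋) summarizes the asymmetry; above 0.5 it inflates learned values
of high-variance options, producing pro-variance choice in *both* good and
bad environments equally.

**PEIRS.** Tracks V (rate α_Q) and expected spread S ← S + α_S(|δ| − S),
S initialized at S₀. Decision values are V′ = V + tanh(ω·d)·S with
d = (V_a+V_b)/2 − 0.5. Because d is positive when both offered options beat
the global mean and negative otherwise, ω > 0 yields spread-seeking in good
environments and spread-aversion in bad ones (and conversely for ω < 0).

**Bayesian-CVaR.** The belief about a deck is a density over the rescaled
value axis, held on a uniform grid of 481 points spanning [0.01, 0.99] (one
point per 0.25-card step, containing every rescaled card value exactly;
grid size configurable). It is the Bayesian estimate of the deck's *value
distribution*: a uniform Dirichlet prior with unit concentration — the flat
Beta(1,1) start — whose posterior mean after t outcomes is

    belief_t = (flat + Σ_i kernel(R_i)) / (1 + t),

updated recursively as belief ← (c·belief + kernel(R))/(c+1) with c the
effective observation count. Each outcome's kernel is the Beta density with
mean R and fixed variance `updatevar` (default 0.009, giving a smoothing
bandwidth of about one card); its shape parameters come from inverting the
Beta moment map, α = Rν, β = (1−R)ν with ν = R(1−R)/updatevar − 1, which is
feasible for every rescaled card value at the default updatevar. The belief
therefore converges to the kernel-smoothed empirical outcome distribution
while the prior washes out as 1/t — broad decks end with broad beliefs,
narrow decks with narrow ones, which is what gives the risk parameter its
leverage.

Decision values are the Conditional Value at Risk of the belief at level
η ∈ (−1, 1): compute the CDF, locate the Value at Risk as the smallest grid
point whose CDF reaches 1+η (η ≤ 0) or η (η > 0), and take the
belief-weighted mean of the tail at or below (η ≤ 0) / at or above (η > 0)
the VaR point, inclusive of it on both branches. η = 0 routes through the
first branch (CDF ≥ 1) and returns the full-belief mean; η = −0.95 reads
the mean of the lowest 5% of belief mass, η = +0.95 the top 5%. On a
discrete grid the inclusive tail makes CVaR slightly conservative (pulled
toward the mean) relative to the continuous ideal, by at most one grid
cell's mass.

### Numerical choices

* Evidence kernels are discretized as per-cell probability masses (CDF
  differences between cell midpoints, end cells absorbing the tails to 0
  and 1), not pointwise density values. For edge cards the kernel's Beta
  shapes drop below 1 and its density diverges at both support ends;
  pointwise evaluation there misplaces mass badly (a kernel with mean 0.99
  would acquire a spurious mode near 0), whereas cell masses preserve the
  kernel mean for every card.
* Beliefs are renormalized to sum 1 (tolerance 1e-9) after every update;
  updating raises an error on an unnormalized input rather than silently
  renormalizing it.
* CDF threshold comparisons use a 1e-12 slack so that exact-mass boundaries
  (e.g. a uniform belief at η = −0.95) resolve to the intended grid point
  despite floating-point cumsum error.
* Choice probabilities inside likelihoods are floored at 1e-12 with a
  warning; softmax exponentials are guarded against overflow.

## Simulation studies

The sweep study runs four conditions — both-narrow (NHNL), both-broad
(BHBL), both-high (BHNH), both-low (BLNL) — with 500 freshly drawn blocks
of 30 trials per condition. The swept parameter is the model's signature
parameter (α; positive learning bias; ω; η); all other free parameters are
marginalized on an even lattice over their transformed prior ranges
(default 9 points; the dual-rate model sweeps the positive bias directly
and marginalizes the overall learning-rate scale). Outcome streams are
derived only from the seed and condition, so every model and parameter
setting sees identical events, and the uniform variates that realize
choices are shared across parameter settings as common random numbers —
learning is choice-independent under full feedback, so this is purely a
variance-reduction device for cross-parameter comparisons. Reported
percentages pool all trials of all blocks.

Expected qualitative pattern (all reproduced by the test suite): the
mean-tracking model is flat at ~50% broader-option choice in the same-mean
conditions; the dual-rate model's pro-variance bias rises monotonically
with the positive learning bias, identically in good and bad environments;
PEIRS with ω > 0 is pro-variance in both-high and anti-variance in
both-low (signs flip with ω); the Bayesian-CVaR model's pro-variance bias
rises monotonically with η in both conditions, with both-high at or above
both-low at matched η.

## Fitting and model comparison

Only the four same-mean blocks enter the likelihood (different-mean blocks
are near ceiling and mostly uninformative about risk preferences); state
resets at every block start. Estimation is bounded maximum a posteriori
with uniform priors over the transformed ranges, which therefore act as
hard box bounds:

| parameter | transform | transformed range | natural range |
|---|---|---|---|
| α, α₊, α₋, α_Q, α_S | logit | [−4.6, 4.6] | (0.0100, 0.9900) |
| β | log | [−3, 3] | (0.0498, 20.1) |
| ω | identity | [−10, 10] | same |
| S₀ | log | [−4.6, 0] | (0.01, 1] |
| η | scaled logit | [−7, 7] | (−0.998, 0.998) |

`updatevar` stays fixed at 0.009 during fitting (a hyperparameter, not a
free parameter). Optimization is multi-start (default 10: the box centre
plus 9 seeded uniform draws) bounded Powell search in the transformed
space. Powell rather than a quasi-Newton method because the CVaR readout is
piecewise constant in η — the VaR index moves only when the belief CDF
crosses a mass threshold — so finite-difference gradients vanish between
thresholds; direction-set search is insensitive to this. For the
Bayesian-CVaR model the belief trajectory is independent of (η, β) and is
cached per subject (per-trial CDF and first-moment partial sums), making a
likelihood evaluation O(trials).

Comparison uses BIC = k ln n − 2 ln L̂ with n the subject's fitted trial
count (120 when complete) and k the free-parameter count (2/3/5/2), summed
over subjects; ΔBIC subtracts the best model's sum. The random baseline
sets every choice probability to 0.5 with k = 0 (BIC = 2n ln 2).

## Synthetic cohorts

A cohort draws each agent's generating parameters uniformly from per-model
ranges (defaults: learning rates 0.1–0.9, β 2–10, ω ±8, S₀ 0.02–0.5,
η ±0.8 — mid-range values that produce neither random nor deterministic
choice), simulates all eight blocks, and attaches a trait score. For CVaR
cohorts the trait is linear in η with negative slope plus Gaussian noise
(defaults: intercept 55, slope −30, noise sd 8, chosen to put scores in a
rumination-questionnaire-like range with a planted correlation of roughly
−0.85); other models receive the same trait distribution with no parameter
link, as a null control. Per-agent RNG streams derive from one cohort seed,
so cohorts are bit-reproducible.

What the generator does *not* emulate: within-subject nonstationarity
(fatigue, attention lapses), block-order effects, response times, the
psychometric structure of real questionnaires (a single noisy linear trait
stands in for a summed item score), and model mismatch (real subjects are
not exact instances of any of the four models). Passing recovery and
pipeline tests on these cohorts therefore demonstrates internal consistency
of the estimation machinery — identifiability at realistic trial counts —
not that human data would be fit this well.

## Exclusions and behavioural measures

Subjects are excluded when mean accuracy across the four different-mean
blocks is strictly below 60%, or when any same-mean block contains 30
identical choices; incomplete subjects are flagged separately rather than
silently dropped, and the exclusion log records which rule fired. The
pro-variance bias is the unweighted mean of the four same-mean block
broader-choice rates (unimodal-only and bimodal-only sub-means are also
exposed). Trait associations use two-tailed Pearson correlation with the
exact t-transform p-value and no multiplicity correction; the pipeline
emits the per-subject table from which any further group statistics can be
computed with standard tools.

## Problem sizes

Defaults used by the test and acceptance machinery: sweeps at 500 blocks ×
30 trials per condition (directional benchmarks use a reduced 3-point
nuisance lattice); recovery at 50 agents with 10 restarts; model confusion
at 30 agents per family with 5 restarts; the trait pipeline at 40 agents.

## Known limitations

* The deck shapes (variances, bimodal geometry, symmetric supports) are
  package conventions; only the means, the mean/variance orderings and the
  support are hard constraints.
* The belief grid is fixed within a block and the readout inherits a
  quantization of one grid cell; results should be checked for stability in
  grid size rather than assumed (481 and 961 points give visually identical
  sweeps).
* η near ±1 is weakly identified at 120 trials when β is small — extreme
  tail readouts change few choices — which bounds achievable recovery
  correlations.
* PEIRS is hard to distinguish from the single-rate model at moderate ω
  (its three extra parameters cost 3 ln 120 ≈ 14 BIC points per subject),
  so confusion studies may attribute PEIRS-generated cohorts to the
  simpler model.
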