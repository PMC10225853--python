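# Methods

`dcrange` infers demography–climate relationships (DCRs) from site×year
abundance counts by Bayesian calibration of a spatially explicit,
individual-based population model, and attributes simulated population trends
to observed climate trends by counterfactual simulation. This note documents
the model, its assumptions, the tunable quantities, the numerical choices,
and what the synthetic test bed does and does not establish.

## Population model

The landscape is a regular grid of 1-km cells. Each cell carries an integer
habitat-suitability index `h ∈ {0, …, 100}` (the count of habitat-classified
100-m cells it contains). The population is female-only with two stages,
juvenile and breeding adult, and a one-year stage transition. Within each
simulated year the processes run in fixed order:

1. **Reproduction.** Each cell with `n` adult females produces
   `Poisson(n · ρ(n))` juveniles, where
   `ρ(n) = ρ_max · exp(−n · b·100/h)`. `ρ_max` is the low-density fecundity
   from the DCR (below), `b` the overall strength of density dependence
   (`1/b` is resource availability) and `h` modulates it locally; cells with
   `h = 0` are sterile. Density is censused pre-breeding. The Poisson
   offspring distribution is the standard choice for stage-structured
   individual-based fecundity; the model carries no Allee effect.
2. **Natal dispersal** in three stages. Each juvenile emigrates with
   probability `p_e`; an emigrant draws a distance from an exponential kernel
   with mean `d̄` (km) and a uniform direction, measured from the natal cell
   centre. It settles in the destination cell if suitable (`h > 0`);
   otherwise in a uniformly chosen suitable cell among the destination's
   eight neighbours; otherwise it dies. Endpoints beyond the grid die, so the
   grid should carry a boundary buffer around the region of interest;
   dispersal mortality is additive to annual juvenile mortality.
3. **Survival and transition.** Each juvenile survives with its settlement
   cell's `s_j`, each adult with `s_a`; surviving juveniles mature.

Individuals within a stage and cell are exchangeable, so the per-individual
draws are realized as per-cell Poisson/binomial variates — distributionally
identical to per-individual Bernoulli draws and much faster. A per-individual
reference mode exists and is exercised by equivalence tests. The default
simulation engine is a compiled (numba) annual-cycle kernel; the plain numpy
implementation of each process is retained as the reference and the two are
checked against each other in distribution.

## Demography–climate relationships

Five seasonal predictors, standardized to z-scores, drive the three rates
through GLM-type links:

| rate | link | predictors (polynomial order) |
|---|---|---|
| fecundity `ρ_max` | log | breeding-season mean temperature `T_br` (2), breeding-season precipitation `P_br` (2) |
| juvenile survival `s_j` | logit | autumn mean temperature `T_at` (2), winter precipitation `P_wn` (2) |
| adult survival `s_a` | logit | winter minimum temperature `T_wn` (1), winter precipitation `P_wn` (2) |

Winter minimum temperature is excluded from `s_j` because it is strongly
collinear with autumn temperature (the `check_collinearity` helper flags such
pairs); its linear-only entry for `s_a` keeps that rate monotone in winter
temperature. Quadratics are plain squares of the standardized predictor, not
orthogonal polynomials. That gives 14 coefficients; with `b`, `p_e`, `d̄` and
the observation dispersion `σ`, 18 parameters are calibrated jointly.

Seasonal aggregation: breeding season is April–July, autumn
September–November, winter December–February, with December taken from the
previous calendar year. Standardization pools one mean and standard deviation
per predictor over all cells and all reference years, preserving spatial
gradients in z-units — appropriate because the DCRs are shared across space.
(A per-cell standardization would discard exactly the spatial contrast the
model needs.) Fecundity is expressed per adult female (one breeding pair ≡
one adult female); any per-pair/per-female factor is absorbed by calibration.

## Observation model and likelihood

Observed counts are linked to simulated adult females by a negative-binomial
likelihood with mean `μ` and variance `μ + μ²/σ`. Because the simulator is
stochastic, the likelihood is an estimate; two standard variance-reduction
devices are applied before it is evaluated: counts and predictions are
spatially aggregated to large blocks (configurable `block_size`, 25 cells in
a full-scale application; 5 cells in the desk-scale studies here), and the
simulated block means are averaged over replicate runs (`n_reps`, 20 at full
scale, 5 at desk scale). A mean floor of 1e-6 keeps the likelihood finite
when extinction is predicted at a block with a positive count.

Three support truncations bound the computational cost of calibration
without touching the posterior where it matters. First, the default prior on
`b` is truncated below at 0.01: `1/b > 100` would imply local carrying
capacities of thousands of breeding pairs per 1-km cell, outside the
territorial-bird regime this model targets. Second, because the survey is a
(systematic-)random sample of cells, the surveyed-cell mean count estimates
the landscape mean; a parameter vector whose simulated population crosses a
ceiling (default five times the count-implied landscape abundance, enforced
within the year on offspring production as well as on adults) claims that
most of the population hides off-sample, contradicts the survey design, and
is treated as outside the support with its simulation aborted. Third, the
likelihood is accumulated year by year and evaluation stops once it falls a
configurable number of nats per block-year (default 20, versus 2-3 for a
well-fitting model) below zero — a floor far beneath any competitive fit.
Together these keep hopeless proposals from dominating wall time; the
within-year offspring guard also protects against the `exp(+50)` fecundity
values the clipped log link still admits at the prior's edge.

The block size should scale with the landscape: the reference design uses
25-km blocks on a roughly 300-km landscape. Desk-scale studies on a 30-cell
grid therefore use 5-cell blocks, preserving the blocks-per-landscape
proportion; collapsing such a landscape to 9 blocks discards the spatial
contrast that identifies the DCRs.

## Priors and sampling

DCR slope coefficients take mildly regularizing truncated normals 0 ± 1 on
[−5, 5]; the dispersion takes a truncated normal 50 ± 50 on (0, 500].
Intercepts and (`b`, `p_e`, `d̄`) take user-configurable (truncated) normals —
in a real application these carry trait-derived information; the defaults are
weakly informative values plausible for a short-lived passerine
(`fec_0 ~ N(0.5, 0.5)`, `sj_0 ~ N(0, 0.75)`, `sa_0 ~ N(0.5, 0.75)`,
`b ~ N(0.1, 0.1)` on [0.01, 5], `p_e ~ N(0.3, 0.2)` on [0, 1],
`d̄ ~ N(2, 1.5)` km on [0.05, 30]).

Informative intercept priors are not a convenience but part of the method:
different combinations of fecundity and the two survival rates produce
near-identical abundance trajectories, so counts alone cannot separate them —
with diffuse intercepts the posterior happily swaps juvenile-survival
response for adult-survival response. `trait_informed_priors()` builds the
prior set a trait-informed analyst would use, centring the three intercepts
(link scale, sd 0.25) and the demographic/dispersal parameters on a reference
vector that plays the role of the published trait compilation; recovery
studies use it with the generating archetype as the reference. Slope priors
stay at the regularizing default — the climate responses are what the data
must identify.

Posteriors are sampled with a differential-evolution MCMC with archive
("z-matrix") sampling and snooker updates (DEzs). Bounded parameters are
sampled on transformed scales (log for `b`, `d̄`, `σ`; logit for `p_e`) with
Jacobian corrections. Internals follow the published defaults of that
sampler family: proposals `x* = x + γ(z₁ − z₂) + ε` with archive states
`z₁, z₂`, `γ = 2.38/√(2d)` and `γ = 1` every 10th generation for mode
jumping, jitter `ε` with scale 1e-4 of the prior spread, snooker probability
0.1 (with the `(‖x*−z‖/‖x−z‖)^(d−1)` acceptance correction), archive seeded
with 10·d prior draws and extended by the population every 10th generation.
Each independent chain runs an internal population of three sub-chains, and
`iterations` counts posterior evaluations per independent chain (so 3 chains
× 20 000 iterations = 60 000 model evaluations) — this matches the iteration
accounting of the R tooling this sampler family comes from. The first half of
every chain is discarded as burn-in. The stochastic likelihood is evaluated
fresh for proposals and cached for the current state (a
`seed_policy="fixed"` option pins the simulation stream instead). Convergence
is declared at a classic Gelman–Rubin PSRF below 1.1 on every parameter (the
threshold is a package choice; the multivariate PSRF is also reported).
Downstream analyses use 400 joint draws from the pooled post-burn-in samples.

With only a handful of likelihood replicates the cached current-state value
makes chains stick to lucky likelihood draws (acceptance collapses to a few
percent). ``reeval_current=True`` refreshes one internal chain's cached value
per generation, round-robin — about a third of an extra evaluation per
proposal — and restores healthy acceptance; recovery studies enable it.

## Evaluation

Four complementary measures, all computed from posterior-predictive
simulations: RMSE of site-level predictions (replicate means at surveyed
cells; block-level optional), Harrell's c-index over all site-years
("spatio-temporal c-index"), a mean yearly spatial AUC after compressing
abundance to presence–absence (replicate-averaged occupancy probabilities;
years lacking both classes are skipped with a warning), and a temporal
c-index comparing the predicted relative total-abundance series (reference
year = first survey year) with an externally supplied abundance index.

## Attribution

Population performance is summarized by the low-density growth rate
`r = s_a/2 + √(s_a²/4 + s_j·ρ)`, the dominant eigenvalue of the two-stage
transition matrix, with fecundity evaluated at one breeding pair per cell.
Two vulnerability measures follow:

* **Partial responses.** Per posterior draw, a base `r` at the median
  predictor values of the occupied range (landscape-wide medians are a
  config option) is compared with `r` after shifting one predictor by its
  observed accumulated trend (OLS slope of the landscape-mean series ×
  survey span, converted to z-units through the standardization record).
  Ratios are classified: |change| < 5% none, 5–10% small, > 10% strong,
  signed.
* **Scenario ratio.** The full model is simulated under the factual climate
  and under a counterfactual obtained by removing the fitted linear trends
  (anchored at the first survey year, i.e. stationary start-of-period
  climate, standardized with the factual record). Per draw both scenarios
  share one master seed (common random numbers) so only the climate signal
  differs; the reported measure is the ratio of mean total adults over the
  final three years, with an 80% interval across draws. Counterfactual
  extinctions are excluded and counted.

## Synthetic data

The generator produces everything the pipeline consumes, with known truth:

* **Climate**: per predictor, a smooth spatial base field (Gaussian random
  field built by wrapped Gaussian smoothing of white noise, normalized to
  unit variance; correlation length 5 cells by default) plus a linear
  temporal trend and spatially correlated interannual noise. Default means,
  spatial spreads, noise levels and trends are chosen to resemble two
  decades of alpine seasonal climate (e.g. +0.05 K/yr breeding-season and
  +0.075 K/yr winter-minimum warming, +1.45 mm/yr winter precipitation —
  about +1 K, +1.5 K and +29 mm accumulated over 20 years).
* **Habitat**: a fine-scale (100-m analogue) field thresholded at the
  requested cover fraction and block-aggregated through the habitat module,
  so `mean(h)/100` tracks the cover fraction exactly and clustering strength
  controls spatial autocorrelation.
* **Initial abundance**: suitable cells are seeded with two adult females
  and spun up for 20 years under first-year climate. This is an explicit,
  reproducible stand-in for initial-abundance models fitted to historical
  survey snapshots; calibration reuses the same initial state, which removes
  initial conditions as a nuisance in recovery experiments.
* **Survey**: one model realization under the true parameters, observed at
  uniformly sampled sites (one count per site-year; repeat-visit summaries
  are assumed to happen upstream) through negative-binomial error, plus a
  total-abundance reference index (noise optional).

Two named parameter archetypes ("mountain", "lowland") ship as fixtures with
contrasting response shapes; they are package fixtures, not empirical
estimates. All randomness derives from counter-based streams keyed by the
master seed, so every artifact regenerates bit-identically.

What the synthetic bed does **not** emulate: observer effort and detection
probability, land-use change, migration, species interactions, and
model-structure mismatch (the generating process *is* the fitted process).
Passing recovery tests therefore demonstrate the correctness and internal
consistency of the machinery — identifiability at the stated data sizes,
sampler validity, attribution nulls — not robustness to the structural
errors real data carry.

## Problem sizes and numerical choices

The desk-scale recovery study uses a 30×30 grid, 15 years, 60 survey sites,
5 likelihood replicates, 5-cell blocks and 3 chains × 20 000 evaluations;
the attribution-null study uses a 20×20 grid, 10 years and 40 sites. These
sizes were chosen as the smallest at which the recovery targets (rate-map
correlation, interval coverage) are statistically meaningful. Linear
predictors are clipped at ±50 before `exp`/`logistic` (overflow guard, not
model content). The mean-field consistency check runs in a
weak-density-dependence regime (`b·n ≈ 0.005`) because the mean-field
projection is exact only to first order in the density-feedback curvature;
the regime keeps that bias far below Monte-Carlo resolution. Growth-rate
ratios at exactly ±5%/±10% classify into the milder class. Ties in the
c-index score one half; pairs tied on the observation are excluded.

## Known limitations

* The fitted DCRs are phenomenological: calibration can compensate for
  structural error, and response shapes should be inspected for plausibility
  before extrapolation.
* Survival and fecundity are only partially identifiable from abundance data
  alone; the regularizing priors matter, and weakly identified coefficients
  shrink toward them. At desk scale (60 sites, 15 years, counts of a few
  pairs per site) this bites hard: the recovery study finds good interval
  coverage of the DCR coefficients and well-ranked abundance predictions,
  but the juvenile-survival response surface itself is essentially
  unidentified — even an oracle variant that fixes every non-slope parameter
  at the generating truth cannot pin it. Cross-rate compensation of this
  kind is an inherent property of calibrating stage-structured models to
  counts, not a sampler artifact (independent chains agree).
* The pseudo-marginal construction uses a replicate-averaged plug-in mean
  rather than an unbiased likelihood estimate; with 20 replicates and block
  aggregation the residual bias is small but not exactly zero.
* Common-random-number coupling across scenarios is exact only while both
  trajectories consume the same draw sequence; after divergence it reduces,
  rather than removes, Monte-Carlo variance in the ratio.
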