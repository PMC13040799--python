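# Methods

## Model

A mixed Gaussian phylogenetic model (MGPM) is a rooted ultrametric tree
whose edges are partitioned into K regimes, each carrying one Gaussian
diffusion for a univariate continuous trait: Brownian motion
(BM, parameter σ) or Ornstein–Uhlenbeck (OU, parameters α, θ, σ).  Regimes
may be disconnected edge sets.  Edges are identified by their child node;
regimes are constant along an edge and switch exactly at nodes; the root
carries no regime — the root state X₀ is a free parameter shared by all
regimes, and the first transition on each root-adjacent edge uses that
edge's regime.  Trait values are observed only at the tips and are assumed
pre-transformed to the real line (log scale for sizes).

Both processes have transitions of the form `x_child | x_parent ~
N(a·x_parent + b, V)` with the mean linear in the ancestor and the variance
free of it, so the tip vector is multivariate normal given Θ and the tree.
The flat parameter vector is Θ = (X₀, Θ₁, …, Θ_K) with (σ) per BM regime
and (α, θ, σ) per OU regime.  The likelihood conditions on X₀ as a
parameter: no root-state integration and no stationarity assumption at the
root.

## Likelihood

`pruning_loglik` passes log-quadratic messages q(x) = ½px² + mx + c from
tips to root.  A tip contributes the transition density viewed as a
function of its parent's state; an internal node sums its children's
messages and integrates its own state against its edge's transition in
closed form:

    p' = p/(1−pV),  m' = m/(1−pV),
    c' = c + ½m²V/(1−pV) − ½log(1−pV),

followed by the affine substitution x ← a·x_parent + b.  Since p ≤ 0 and
V ≥ 0, the denominator 1−pV ≥ 1, so a zero-variance *internal* edge
composes exactly (Dirac transport) with no special-casing.  A
zero-variance *terminal* edge would make the likelihood atomic in the
data, so a zero-length pendant edge raises an error, and a
parameter-induced variance underflow returns −∞ (invalid parameter
region).  `dense_loglik_oracle` rebuilds the full tip mean/covariance by a
pre-order recursion and evaluates the multivariate normal directly; it is
an independent O(n³) cross-check used throughout the tests (agreement to
1e−8 absolute on hundreds of random mixed-regime instances).

OU coefficients switch to a first-order series in αl below αl = 1e−8 to
avoid 0/0 in (1−e^{−2αl})/(2α); the BM limit α → 0 is continuous.

## Priors and transform

Parameters are a priori independent; the joint prior is a product of
per-parameter densities.  Positive parameters (α, σ) are log-transformed,
unconstrained ones (X₀, θ) pass through identity; all inference runs in
the resulting unbounded space with the exp-Jacobian included, so the
transformed prior has full support on ℝᵈ.

Calibration recipes map interpretable anchors to hyperparameters:

- `normal_from_quantiles` pins a Normal by two stated quantiles of the
  plausible trait range (used for X₀ and θ).
- `alpha_prior_from_halflife` converts the shortest plausible phylogenetic
  half-life fraction into the rate α* = ln2/(fraction·t_H), set as an upper
  quantile of a Half-Normal.
- `sigma_prior_from_tip_variance` converts a plausible tip variance into
  the BM-equivalent diffusion σ* = √(tip_var/t_H), likewise an upper
  quantile.

Shipped presets: `diffuse` (Half-N(10) on positives, N(0, var 100) on
reals), `moderate` (Half-N(5), N(0, sd 5)), `antler` (the worked
calibration: N(1.9560, var 2.3295), Half-N(2.5210) on α, Half-N(0.2940)
on σ).

## Posterior simulation

`pmc_sample` is a fixed two-stage Population Monte Carlo pipeline:

1. **Laplace stage.** Multi-start quasi-Newton maximization of the
   unbounded-space log-posterior (starts drawn from the prior; L-BFGS-B
   with tight tolerances), central finite-difference Hessian at the mode
   (relative step 1e−4; stable across 1e−5…1e−2 in our checks).  If −H is
   not positive definite its eigenvalues are floored at 1e−8 times the
   largest and the repair is flagged in the diagnostics.
2. **Importance stage.** S iid draws from the Laplace Gaussian, weighted by
   posterior/proposal with log-sum-exp normalization; the ESS of these
   weights is the sampler's principal quality diagnostic.  An optional
   scalar inflation of the proposal covariance exists but is off by
   default.
3. **Resampling.** S multinomial draws by the stage-1 weights.
4. **Rejuvenation.** Each resampled particle is perturbed once by a
   Gaussian kernel centred on it with shared diagonal covariance
   (1/S)·diag of the empirical coordinate variances of the resampled set.
   The default accepts the perturbation by a Metropolis ratio
   (`rejuvenation="move"`), reusing the stage-1 posterior values so one
   pass costs exactly 2S posterior evaluations beyond the Laplace stage,
   and returns equal weights.

Two importance-reweighting variants of stage 4 are retained for reference
and regression-tested, because their failure mode shaped the design.
Writing the perturbed particle as θᵢ = cᵢ + σ_k Zᵢ, the weight against the
particle's *own* kernel is

    log w*ᵢ = log π(cᵢ + σ_k Zᵢ) − log N(θᵢ; cᵢ, σ_k²)
            ≈ log π(cᵢ) + |Zᵢ|²/2 + const,

i.e. it contains the particle's own standardized jump |Zᵢ|²/2 — a χ²-
distributed term independent of the target.  E[exp(χ²/2)] diverges, so the
weight variance is infinite under the 1/S-scaled kernel and the ESS
plateaus at a small constant regardless of S (measured: ESS ≈ 28 at
S = 5000 on a 1-D conjugate target where stage 1 attains ESS = S).  The
kernel-mixture (balance-heuristic) denominator repairs this wherever the
particle cloud is dense but inherits the same pathology at isolated tail
atoms.  The symmetric-kernel Metropolis correction sidesteps the weighting
entirely: it leaves the posterior invariant, so it can only improve the
resampled approximation, at the same evaluation cost.

Reported Monte Carlo standard errors use the self-normalized
importance-sampling delta method, floored at sd·√(2/ESS₁) (ESS₁ = stage-1
ESS): the binding sample size after resampling is ESS₁, and one multinomial
resampling step doubles the asymptotic variance.

Reproducibility: a single master seed spawns independent per-stage RNG
streams; all random draws precede the posterior evaluations, so threaded
evaluation (`n_jobs`) cannot change the result.

## Summaries

Posterior summaries are computed on back-transformed (original-space)
draws: weighted mean, sd, MC standard error, and 2.5/50/97.5% quantiles by
inverting the weighted step-function ECDF without interpolation (atoms
carry their full mass; left-continuous).  Equal-tailed credible intervals
use the same quantile convention.

## Predictive checks

Posterior predictive replicates are drawn in two steps: multinomial
resampling of parameter vectors by the final weights, then one pre-order
forward simulation of the tree per vector.  The posterior predictive loss
is SSE + λ·(summed per-tip replicate variances); λ = 1 is the plain score
and λ ∈ {ln p, p} (p counts all parameters including X₀) penalizes
complexity explicitly.  Per-tip predictive densities are computed exactly —
each resampled draw contributes a normal with mean/variance composed along
the root-to-tip path — rather than by kernel density estimation of
simulated tips; draws enter with equal weight after resampling.

## Synthetic data and study harness

`random_ultrametric_tree` generates pure-birth (Yule) trees rescaled to
unit height; `random_clade_painting` draws seeded clade regimes (stem edge
included, later declarations overriding earlier ones).  These fixtures
emulate the shape of empirical time-calibrated phylogenies but not their
imbalance or their node-age distribution: a Yule tree has many short deep
branches, which weakens the identifiability of OU rates relative to an
adaptive-radiation tree of the same size.  Passing tests on these fixtures
therefore demonstrate correctness of the machinery and qualitative
behaviour of the method, not its calibration on any particular empirical
tree.

The studies module re-runs three seeded experiments at configurable scale
(defaults: a 50-tip unit-height fixture, 20 replicates and S = 5000 for
parameter recovery, 10 replicates and S = 2000 for the 3×3 model-evaluation
design — sizes chosen so each study completes in minutes on one core):

- **Parameter recovery**: truth X₀ = 0, Ancestral OU(2, 2, 1), derived
  regime OU(5, 0, 0.5), diffuse priors; records posterior medians, 95%
  intervals, coverage, and a box-constrained multi-start ML comparator
  (random starts uniform in the box, [0, 100] for positive parameters,
  [−200, 200] for X₀ and θ).
- **Model evaluation**: nested one-/two-/four-regime OU models with fixed
  truth tables, cross-fitted, scored by PPL at λ ∈ {1, ln p, p}.
- **Prior sensitivity**: the recovery scenario under three progressively
  tighter prior configurations.

## Known limitations

- The one-pass Laplace-Gaussian importance sampler cannot represent
  posterior mass far outside the Laplace Gaussian.  OU posteriors on short
  trees have a rate–optimum "funnel": when the data cannot exclude slow
  adaptation (small α), θ's conditional spread approaches its prior.  On
  the 50-tip recovery fixture an MCMC reference shows exact-inference
  coverage of ~95%, while the PMC intervals under-cover the root-adjacent
  regime's parameters (~50–70% for its α, σ, θ at 20 replicates; the
  derived regime and X₀ reach 85–100%).  Iterated adaptation, tempering,
  or MCMC moves would close this gap but are deliberately outside this
  package's scope.
- Posterior medians of α are biased upward on such fixtures (mass at large
  α is retained by the Half-Normal prior); this mirrors the behaviour of
  the ML comparator, which instead collapses to the α → 0 boundary or
  escapes to large values depending on the replicate.
- No tip measurement-error term; no missing data at tips; regimes and tree
  are fixed, not inferred; traits are univariate.
- Non-ultrametric trees are rejected by default (prior calibration assumes
  a single height t_H); validation tolerance is configurable.
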