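# Methods

## Model

The outcome is a six-way classification of each survey respondent by
diabetic status crossed with weight status; category 6 (normal weight,
non-diabetic) is the reference. For respondent *i* the *J* = 5 morbid
categories get linear predictors

φ_ij = α_j + β_{j,r_i} + γ_{j,e_i} + η_{j,a_i} + Σ_k δ_{jk} x_{k,C_i} + λ_j v_{C_i} + κ_j u_{S_i},

mapped to probabilities by the multinomial logit with the reference fixed at
0. Race (4 levels, white non-Hispanic reference) and education (4 levels,
less-than-high-school reference) are fixed effects under corner constraints.
The five county covariates are the poverty proportion, log population
density, and three binary indicators for counties in the top decile of
black, Hispanic and other-nonwhite population share (an indicator is 1 when
the county's share strictly exceeds the order statistic at position
ceil(0.9·n); with distinct values exactly floor(n/10) counties are coded 1,
ties at the threshold are coded 0).

Survey weights enter the posterior through the weighted pseudo-likelihood
Σ_i w_i Σ_j d_ij log π_ij. `weighted_loglik` uses the weights exactly as
supplied; `run_mcmc` by default rescales them to mean 1 (sum = n) so the
prior/likelihood balance reflects the actual sample size, with a raw-weights
option. An observed-category probability that underflows to zero yields a
log-likelihood of −inf (never an exception), so Metropolis steps simply
reject.

### Latent spatial structure

Unmeasured area influences are two shared factors: a county field v and a
state field u, each entering every category through free loadings (λ_j, κ_j
for j ≥ 2; λ_1 = κ_1 = 1 fixes the factors' scale). Both fields carry
intrinsic CAR (ICAR) priors with binary adjacency: the pairwise-difference
kernel −(1/2σ²) Σ_{i~j} (x_i − x_j)², proper on the sum-to-zero subspace of
each connected component, with isolated nodes given independent
Normal(0, σ²) terms. The normalised log density equals the degenerate
Gaussian with precision L/σ² (L the graph Laplacian, rank n −
n_components); the log pseudo-determinant is cached per graph. Sampling in
the generator uses the spectral construction on the non-null eigenspace, so
draws have covariance σ²·L⁺ and sum to zero per component.

### Priors

The source analysis does not state its priors, so the following defaults
(all configurable via `PriorConfig`) are the package's own choices:
Normal(0, 10²) on every free fixed effect and loading; half-Normal(0, 1) on
the conditional standard deviations σ_v, σ_u (heavier-tailed Gamma priors on
precisions are a common alternative but mix worse when a field is weak); a
first-order random walk over the 12 age groups for η with cross-category
innovations ε_a ~ MVN(0, Σ_η), Σ_η ~ inverse-Wishart(J + 2, I) — this gives
smooth, mutually correlated age profiles — identified by sum-to-zero
centering within category.

## Inference

`run_mcmc` is an adaptive Metropolis-within-Gibbs sampler (two chains of
10,000 iterations by default, first half burn-in). Design elements:

* **Sufficient statistics.** Respondents are collapsed to (age, race,
  education, county) cells with survey-weighted outcome counts, making one
  likelihood evaluation O(n_cells × 6) regardless of sample size.
* **Incremental likelihood state.** exp(φ), the multinomial denominator and
  per-cell log-likelihoods are maintained incrementally and refreshed every
  200 sweeps; overflowing proposals produce −inf increments and are
  rejected, so the current state stays finite. (The public likelihood
  functions use overflow-safe log-sum-exp throughout.)
* **Coloured single-site updates.** Parameters that are conditionally
  independent given the rest — counties within one colour class of the
  adjacency graph, even/odd age indices under the RW1 prior, race or
  education levels — are proposed and accepted simultaneously in one
  vectorised pass.
* **Covariate standardisation.** County covariates are standardised by
  their respondent-weighted moments inside the sampler (draws are recorded
  on the original scale), which near-orthogonalises δ and α in the
  likelihood metric. δ blocks additionally use empirical-covariance
  (Haario-type) proposals learned during the second half of burn-in.
* **Ridge and symmetry moves.** The factor structure creates well-known
  weakly identified directions; each gets an exact Metropolis move:
  (i) joint rescaling v → s·v, λ_{j≥2} → λ_j/s, σ²_v → s²σ²_v (only
  category 1's likelihood changes), and the state-level analogue;
  (ii) likelihood-invariant shears v → v + h·x_k, δ_{jk} → δ_{jk} − h·λ_j
  along each covariate column (prior-only acceptance);
  (iii) level shifts α_j → α_j + h with the corner-constrained race or
  education block shifted by −h (only reference-level cells change);
  (iv) sign reflections (v, λ_{j≥2}) → (−v, −λ_{j≥2}) and the state
  analogue, crossing the near-symmetric reflection modes of a weak factor;
  (v) independence proposals from the prior for each free loading, which
  mix instantly when a loading is weakly identified.
* **Adaptation** is Robbins–Monro per block (targets 0.44 scalar / 0.25
  block) in windows of 50 iterations and is frozen at the end of burn-in,
  preserving detailed balance for the recorded draws.
* **Constraints** (sum-to-zero η, v, u; corner constraints) are re-applied
  after every sweep with the removed means absorbed into the intercepts, so
  the likelihood value is untouched.
* **Initialisation** uses empirical weighted log-odds for the intercepts
  plus dispersed perturbations (factor 1 for chain 1, 3 for chain 2); a
  non-finite starting posterior is re-drawn up to 20 times.
* **Variance parameters** are updated on the log scale with the appropriate
  Jacobian; Σ_η has a conjugate inverse-Wishart Gibbs update.

Diagnostics: Gelman–Rubin PSRF with the small-sample correction
(V̂ = (n−1)/n·W + (1+1/m)·B/n), reported for the structural parameters the
analysis tabulates (α, β, γ, δ, η, loadings, log variances); the latent
fields can be included on request. Posterior summaries report mean, sd,
batch-means MC error (50 batches) and 2.5%/97.5% quantiles. DIC = D̄ + pD
with pD = D̄ − D(posterior mean of all parameters); pD can be negative when
a badly misspecified model is forced onto the data (e.g. the baseline model
on full-model data) and is then reported verbatim with a warning.

## Synthetic data

The generator emulates the structure of a BRFSS-like survey of adult males:

* **Geography**: counties on the most-square rook lattice, states as
  contiguous snake-order blocks, state adjacency induced from county
  adjacency. Real shapefile geography is out of scope.
* **County covariates**: poverty ~ Beta(2.5, 14) (mean ≈ 0.15), log density
  ~ Normal(4, 1.5²), race composition ~ Dirichlet(8, 1, 1, 0.5) with
  top-decile indicators computed by the coding rule above. County
  population sizes are log-normal (σ = 1), mimicking the very unequal
  county sizes of real US geography, and respondents are allocated
  proportionally.
* **True parameters** default to magnitudes typical of fitted multilevel
  analyses of obesity–diabetes comorbidity in US men: intercepts matching
  overall category shares of (4.2, 3.1, 1.4, 22.4, 40.2, 28.8)%; higher
  morbidity for black and Hispanic men; lower morbidity for college
  graduates; a strong positive county-poverty effect on the obese-diabetic
  category; lower morbidity in denser counties; rising age profiles for the
  diabetic categories and near-flat ones otherwise; county loadings
  (1, 1.25, 1.27, 2.44, 1.65), state loadings (1, 1.09, 0.45, 0.48, 0.30);
  conditional variances σ²_v = 0.3 and σ²_u = 0.1 (the state level the
  weaker of the two).
* **Survey weights**: a stratified design on age × race. Covariate strata
  are drawn from the population distribution tilted by per-stratum sampling
  probabilities (older and white respondents over-represented, as in
  telephone surveys) and weights are the inverse sampling probabilities,
  optionally jittered. `population_category_shares` enumerates the exact
  design-based oracle the weighted estimates should recover.

What the generator does **not** emulate: real adjacency irregularity,
post-stratification raking, cluster sampling, item nonresponse, or
measurement error in self-reported height/weight. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model, not robustness to the misspecifications real BRFSS data contain.

## Study sizes used in the tests

The replicate recovery study (and the acceptance script) uses 96 counties
in 12 states with 8,000 respondents per replicate, five replicates, two
chains of 4,000 iterations per fit. These sizes were chosen as the smallest
configuration at which every level of the model is genuinely identified:
with very few states (4–5) the rank-one state factor κ_j·u_s has
likelihood-equivalent decompositions and a genuinely multimodal posterior,
so state loadings are not interpretable at that scale regardless of sampler
quality. At 96/12 the study gives ≈ 93% credible-interval coverage of the
generating fixed effects, county-field recovery correlations ≈ 0.76–0.94,
the correct DIC ordering in every replicate, and PSRF ≤ 1.07 on all
reported parameters of the full-model fits.

## Numerical choices and edge cases

* Category probabilities and public likelihoods use log-sum-exp; the
  saturation limit (φ → ±∞) returns probabilities 1/0 with row sums exactly 1.
* The decile rule's tie convention (strict inequality above the
  ceil(0.9·n) order statistic) flags exactly 311 of 3,110 distinct values
  and flags nothing when all values are equal.
* Isolated graph nodes are permitted and flagged; they carry proper
  Normal(0, σ²) priors in the kernel and come out exactly 0 from the
  spectral sampler.
* log σ² is confined to (−30, 30) during sampling to avoid degenerate
  floating-point states when a field collapses.
* The marginal latent variance var_i(λ_{j(i)} v_{C_i} + κ_{j(i)} u_{S_i})
  needs a convention for reference-category respondents, who have no latent
  term of their own: by default they contribute the category-share-weighted
  average of the J composite effects (an explicit approximation to an
  under-specified quantity); restricting to morbid-category respondents is
  available as an option.
* Age standardisation of cross-tabulations is direct standardisation to the
  overall weighted age distribution of the sample; group-age cells with no
  observations are renormalised over the ages present.
* Printed-style tables round half-up to one decimal; posterior prevalence
  tables default to the mean of per-draw probabilities (correct under the
  nonlinear transform), with evaluation at the posterior mean available.

## Known limitations

* The ICAR form, priors and age-effect structure are the package's design
  choices where the methodology leaves them open; alternatives (proper CAR,
  BYM, independent age effects) are not implemented.
* pD (hence DIC) is unreliable for badly misspecified fits; the package
  warns rather than clamps.
* Single-site field updates plus ridge moves are adequate at desk scale;
  very large geographies (thousands of areas) would benefit from block
  updates of the fields, which are not implemented.
* No mapping/choropleth output; results are delimited tables keyed by
  county index.
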