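# Methods

## Model

`depindex` measures deprivation as the subject parameter of a two-parameter
item response model over J dichotomous indicators coded so that 1 is always
the deprivation-associated level. The fitted response function is **probit**,
taken directly from the latent-utility formulation

    x*_ijk = α_jk + β_jk θ_ik + ε_ijk,  ε ~ N(0,1),  x = 1{x* > 0}.

A logistic item characteristic curve parameterised by (inflection, slope) is
a common alternative presentation of the same idea; the two disagree only by
the link function. We fit probit because it is what the latent-normal
statement implies and because it admits exact conjugate augmentation. ICC
summaries preserve the familiar reading through the transformation: the
inflection (the trait value at which endorsement probability is ½) is
−α/β, and β remains the slope scale.

Identification: θ ~ N(0,1) fixes location and scale of the latent metric;
the reflection invariance (θ, β) ↔ (−θ, −β) is removed by constraining every
β_jk > 0, which is substantively justified by the monotone
deprivation-direction coding of the items.

### Priors

No canonical prior specification exists for this model in this setting; the
following are package choices:

* pooled model: α_j ~ N(0, 2²), β_j ~ N(0, 2²) truncated to (0, ∞);
* hierarchical model: α_jk ~ N(μ_j^α, τ_j^α²), β_jk ~ N(μ_j^β, τ_j^β²)
  truncated positive; hypermeans μ ~ N(0, 2²);
* hyper-scales: τ ~ half-Cauchy(1), implemented by the conjugate
  inverse-gamma scale mixture (τ² | η ~ IG(½, 1/η), η ~ IG(½, 1/A²)). With
  only K = 4 provinces the hyper-scale posterior is prior-sensitive; the
  half-Cauchy's mass near zero lets province effects collapse when the data
  are exchangeable while its heavy tail lets genuinely varying items escape
  shrinkage. A plain conjugate Inverse-Gamma(2, 1) prior on τ² is available
  via `IrtModelSpec(hyper_tau_prior="inv_gamma")`.

A caveat shared by both hyperprior forms: the hypermean update for β treats
the province-level β_jk draws as normal observations, ignoring the
1/Φ(μ/τ)^K normalising factor induced by the positivity truncation. The
approximation is negligible whenever μ_β/τ_β is a few units positive, which
holds for discriminations near 1.

## Sampler

Fitting is by Gibbs sampling with latent-utility data augmentation, the
classic scheme for probit models: given the binary responses, each x* is a
one-sided truncated normal; given x*, the trait update is
θ_i ~ N(V_i Σ_j β_jk(x*_ij − α_jk), V_i), V_i = (1 + Σ_j β²_jk)⁻¹; each
(α_jk, β_jk) cell is a two-coefficient Bayesian linear regression with unit
residual variance, sampled by an exact two-block scan (α | β normal, then
β | α positive-truncated normal — the constrained posterior is the invariant
law of that scan); hyper-updates are conjugate normal / inverse-gamma.
Truncated normals are drawn by inverse log-CDF (`ndtri_exp`/`log_ndtr`), so
cells with |α + βθ| > 6 remain finite and correctly distributed.

Plain data augmentation mixes notoriously slowly for low-prevalence items:
the utilities and the intercept move in near-lockstep, and the (α, β)
posterior of a rare item is a long banana ridge. After the conjugate update,
each sweep therefore applies (twice) a **collapsed Metropolis refresh** of
every cell: a symmetric Gaussian proposal on (α_jk, β_jk) targeting
p(α, β | θ, x, hyper) with the utilities integrated out (a two-parameter
probit-regression posterior). The proposal covariance is adapted from the
burn-in trajectory of each cell (Welford running covariance, scaled by
2.38²/2) and frozen at the end of burn-in, keeping the post-burn-in kernel
Markov. The composite kernel's correctness is verified by a Geweke
successive-conditional test (prior-predictive vs Gibbs-forward moments) in
the test suite. Effect: worst-case R-hat on the calibrated cohort drops from
≈1.6 to ≤1.05 at 2 chains × 2500 iterations.

Defaults: 5000 iterations, 2500 burn-in, thinning
1, 4 chains. Initial values are probit-transformed item prevalences for α,
β = 1, standardized row sums for θ, jittered per chain. Every random draw
descends from one master seed through SHA-256-derived per-stage child seeds,
so all outputs are bit-reproducible.

Convergence is monitored by R-hat and effective sample size (arviz) on all
item parameters.

## Model comparison

WAIC = −2(lppd − p_WAIC), with the pointwise unit being one person-item
response conditional on the θ draws (n = N·J cells), lppd by log-sum-exp,
p_WAIC as the sum of pointwise sample variances (divisor S−1), and
SE = √(n·var_i(waic_i)). A streaming implementation (chunked log-sum-exp +
pairwise-combined variance) avoids materialising the S × N·J matrix and is
tested to agree with the dense formula to 1e-8. A difference of 5 is treated
as substantial. The "overall" ICC (the mean curve across provinces) uses the
item's hypermean draws; averaging the province-level curves instead is
available by flag.

## Outcome model

The association between the index and missing the second cohort visit is a
Bayesian logistic regression with independent N(0, 2.5²) priors on
standardized-scale coefficients, sampled by random-walk Metropolis with
proposal covariance adapted during burn-in and frozen after. The index
enters as the plug-in per-person posterior mean of θ (index uncertainty is
not propagated; this matches the two-stage design in which the index is
estimated once and then used as a covariate). Odds-ratio point estimates
are posterior means of the exponentiated draws; intervals are 2.5/97.5%
quantiles. The fixed visit horizon makes a binary outcome appropriate; no
time-to-event modelling is attempted. The same WAIC routine compares the
index-only model with the all-components model.

## Synthetic cohort

The generator is the probit latent-normal model itself, so simulated data
satisfy the fitted model's assumptions exactly. Calibration:

* four provinces with 613/409/563/197 participants;
* nineteen candidate indicators; each cell's intercept solves
  Φ(α/√(1+β²)) = published prevalence, and each cell's MCAR missingness
  rate equals the published missing fraction (0–13%);
* ground-truth discriminations are frozen LogNormal(0, 0.3²) draws from a
  fixed fixture seed, so recovery tests always face the same truth;
* the binary outcome is Bernoulli(logit⁻¹(a + b·θ)) with b = log(1.17) and
  a solved by 1-D root finding so the marginal non-attendance rate is 30%.

What the generator does **not** emulate: informative (MNAR) missingness,
within-province clustering beyond the item parameters, item responses that
violate monotone deprivation coding, misspecified link functions, or
longitudinal visit histories. Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness of the index to real-data violations of them.

## Numerical and degenerate-input choices

* Income dichotomization boundary: exactly $1500/month is non-deprived.
* Province filter default min_n = 100 (drops sites of 13 and 47, keeps 197).
* Items with zero overall variance abort the fit with the item named; a
  province whose trait values are numerically constant raises a degeneracy
  error from the item regression.
* χ² tests are Pearson without continuity correction on pairwise-complete
  rows; tables with a zero margin are flagged degenerate and excluded from
  significance counts.
* MCA uses the indicator-matrix route with D = min(N−1, C−Q) dimensions and
  raw (uncorrected) inertias; for Q binary items total inertia is exactly 1.
* Perfect separation in the outcome model warns and proceeds (the proper
  prior keeps the posterior integrable).

## Known limitations

* With K = 4 provinces, hyper-scale posteriors remain prior-sensitive; WAIC
  comparisons between the pooled and hierarchical variants on *exchangeable*
  data scatter by roughly ±10 at n ≈ 200 per province, because the hierarchy
  cannot distinguish estimation noise from true province variation at that
  size. When true province variation is strong the comparison is decisive.
* The index is cohort-relative: scores are identified only up to the N(0,1)
  trait convention within the fitted sample and do not transfer to other
  cohorts without refitting.
* Complete-case analysis assumes MCAR; no joint model of the missingness
  mechanism is fitted.
* Final item selection is expert input; the package computes the χ²/MCA
  diagnostics but does not automate the choice (default: the nine published
  items).

## Problem sizes used in tests

The test suite runs the cohort-scale checks at 2 chains × 2500 iterations
(recovery) and 2 chains × 2000 iterations at N = 800 (model-selection
replicates); the tiny-instance oracle check integrates a 6-person, 2-item
posterior on a 61×61 grid per item with 41-node Gauss–Hermite quadrature
over the trait. These sizes were chosen so the full suite gives stable
verdicts on a single CPU while preserving each property being tested.
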