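# Methods

## Model

The outcome is a per-subject count (ANC visits in one pregnancy). The
population is assumed to split into two latent groups, each Poisson:

    f(y_i | π, μ₁ᵢ, μ₂ᵢ) = π Pois(y_i; μ₁ᵢ) + (1 − π) Pois(y_i; μ₂ᵢ).

The marginal moments are E(Y_i) = μ_i = πμ₁ᵢ + (1 − π)μ₂ᵢ and
Var(Y_i) = μ_i + π(1 − π)(μ₁ᵢ − μ₂ᵢ)², so the mixing always contributes
non-negative overdispersion. Instead of regressing the two component means
on covariates (which yields latent-class, not population, effects), the
marginalized parameterization regresses the *marginal* mean:

    log μ_i = xᵢ′β,   log μ₁ᵢ = zᵢ′α,   logit(π) = τ,

with μ₂ᵢ recovered by substitution, μ₂ᵢ = (μ_i − πμ₁ᵢ)/(1 − π). Writing
η_i = e^{xᵢ′β}(1 + e^τ) − e^τ e^{zᵢ′α}, the identity
(1 + e^τ)(1 − π) = 1 gives η_i = μ₂ᵢ exactly, and the marginalized
likelihood is the latent-class likelihood with that substitution. The code
exploits this: `marginalized_loglik` is tested to agree with the direct
two-component mixture log-pmf (the internal oracle) to 1e-8 over random
valid parameter sets, and the η-form display is used for computation with
the inner bracket combined by log-sum-exp.

Interpretation: exp(βⱼ) is the incidence density ratio — the ratio of
population-mean counts for a one-unit change in covariate j, all else
fixed. By default the same covariates enter both parts (Z = X), matching
the fitted model this package reproduces; a distinct Z is supported.

## Validity region and penalty

The substitution is only meaningful when μ₂ᵢ > 0 (equivalently η_i > 0) on
every row. The optimizer runs unconstrained, so for invalid parameter sets
the log-likelihood returns −10¹⁰ − Σᵢ max(0, −η_i): a value far below any
attainable likelihood whose slope still points back toward the valid
region, letting BFGS line searches retreat smoothly. A fit whose optimum
touches the penalized region is rejected with instructions to
re-initialize; reported fits have zero validity violations.

## Estimation

1. **EM starting values for (α, τ).** The plain latent-class mixture with
   both component means log-linear in Z is fitted by EM: responsibilities
   from the current component pmfs (E-step), responsibility-weighted
   Poisson regressions and π = mean responsibility (M-step). Initial
   responsibilities split subjects at the outcome median (0.75/0.25), a
   deterministic choice; a random-start mode perturbs it under a seed.
   Convergence is a relative log-likelihood change below 1e-8 or 500
   iterations. The observed-data log-likelihood path is non-decreasing (EM
   ascent), which the tests assert on every run. Labels are fixed by the
   rule "component 1 has the smaller fitted intercept"; π is clamped to
   [0.01, 0.99] for the starting value only, so logit(π) stays finite.
   Both component means are regressed on Z and only component 1's
   coefficients are exported, the simplest choice consistent with needing
   one α vector.

2. **MZIP starting values for β.** A zero-inflated Poisson with
   intercept-only structural-zero probability ψ (logit ψ = γ₀) and
   *marginal*-mean regression log ν_i = xᵢ′β, ν = (1 − ψ)λ, is maximized by
   BFGS from Poisson-regression coefficients. Because both the MZIP and the
   marginalized mixture parameterize the marginal mean, β̂ from one is a
   consistent start for the other. With no zeros in the data the ZIP is
   unidentified and plain Poisson coefficients are returned (warning).
   The zero-model is intercept-only because only the mean part of the MZIP
   is needed for starts.

3. **Quasi-Newton maximization.** BFGS with numerical gradients on the
   joint (β, α, τ) vector; gradient tolerance 1e-6, max 1000 iterations. A
   stop reported as "precision loss" with a final gradient below 1e-2 in
   absolute value is treated as converged — with finite-difference
   gradients BFGS routinely halts this way at machine-precision optima.
   The optimum must not degrade the starting log-likelihood.

4. **Standard errors.** Square roots of the diagonal of the inverse
   negative Hessian of the log-likelihood at the optimum, built from
   central second differences with per-coordinate step
   h_j = max(1e-5, 1e-5·|θ_j|). Components with non-positive curvature get
   NaN SEs plus a warning. Whether published tables used observed or
   expected information is generally unknowable from the table alone, so
   numerical agreement of SEs with any specific published analysis is not
   expected; the Monte-Carlo study below checks calibration instead.

5. **Reporting.** Wald z = β̂/SE with two-sided normal p-values; 95% CIs as
   estimate ± 1.96·SE; IDR = exp(β̂); the mixing proportion is reported on
   the probability scale with the delta-method SE, se(π̂) = π̂(1 − π̂)·se(τ̂).
   Display rounding: coefficients/SE/CI/IDR to 3 dp, p-values to 3 dp with
   a "<0.001" floor. z-values are computed from unrounded internals; a z
   recomputed from rounded β and SE can differ in the third decimal and is
   not a conformance surface.

6. **Baselines.** Log-linear Poisson (statsmodels GLM) and NB2 negative
   binomial (statsmodels, log link) on the same design; AIC = −2ℓ + 2k with
   k = p₁, p₁ + 1, and p₁ + p₂ + 1 respectively. An NB dispersion estimate
   collapsing to zero falls back to the Poisson fit with a warning.

## Descriptive stage

Per covariate level: n, percent, mean count, SE = SD/√n (n − 1 denominator)
and a normal 95% CI (multiplier 1.96, which reproduces published
descriptive CIs at these sample sizes to 2 dp). Association tests are the
classical equal-variance one-way ANOVA; for binary covariates the pooled
t-test is the identical test (F = t²). Stars: \*\*\* p < 0.01, \*\* p < 0.05,
\* p < 0.10, strict inequalities. For multi-level variables the stars come
from the omnibus ANOVA p-value, not pairwise contrasts. Survey weights and
cluster effects are deliberately ignored throughout, matching the unweighted
convention of the analysis this package reproduces.

## Synthetic cohort

The generator emulates the BDHS-like study population so every stage runs
without restricted data:

- **Covariates**: nine categorical variables sampled independently at the
  published marginal proportions (e.g. study continuity 11.2/12.3/76.5%),
  reference level first. Independence across covariates is a simplification
  — the model conditions on covariates, so their joint law does not affect
  estimator correctness, but synthetic descriptive tables will not show the
  real data's cross-covariate confounding.
- **Counts**: drawn from the mixture at true β equal to the published
  coefficient vector and τ = logit(0.61), the published adjusted mixing
  proportion. α is β with the intercept shifted by log 0.6, i.e.
  μ₁ᵢ = 0.6 μ_i, chosen once because (a) it guarantees
  μ₂ᵢ = ((1 − 0.6π)/(1 − π)) μ_i > 0 on every possible covariate profile
  and (b) it yields marginal SD ≈ 2.9 at mean ≈ 3.9, matching the real
  cohort's dispersion (mean 3.93, SD 2.88). The per-subject latent class is
  kept in the output for diagnostics only and never reaches the fitter.
- **Derived variables**: the study-continuity classifier (dropout iff
  years of schooling < 10; among the rest, continued iff still studying
  after marriage) and rank-based wealth tertiles (groups as equal as
  possible, ties broken by stable order of appearance, invariant to any
  strictly increasing transform of the scores).

What passing tests on synthetic data do *not* show: robustness to survey
design (weights, stratification, cluster variation), to covariate
dependence, or to misspecification of the two-component assumption.

## Monte-Carlo calibration

The recovery study simulates n = 3000 subjects with one balanced binary
covariate at β = (1.0, −0.4), α = (0.3, −0.2), τ = 0.4 and runs the entire
pipeline per replicate (100 replicates by default; the acceptance checks
use these sizes, chosen to make the study a few tens of seconds per run).
Checked properties: componentwise |bias(β̂)| < 0.03, empirical 95% Wald CI
coverage within [0.90, 0.98], mean π̂ within 0.03 of logistic(τ), and
AIC(mixture) < AIC(Poisson) in ≥ 95% of the first 50 replicates.

## Numerical choices and edge cases

- All pmf arithmetic in log space; log y! via log-gamma; mixtures combined
  with log-sum-exp. Stable for counts and rates to 10³ and beyond.
- π is attached to component 1 (the α-modeled component) and the label rule
  makes that attachment deterministic; no label switching downstream.
- Tertile ties: stable order of appearance (deterministic, testable).
- Degenerate descriptive cells (n = 1) produce NaN SE/CI with a warning
  rather than an error.
- Complete-case rule on input: rows with any missing declared analysis
  column are dropped and counted; retained rows are never altered.

## Known limitations

- Only the Poisson–Poisson mixture is marginalized; a negative-binomial
  first component (for within-class overdispersion) is out of scope.
- No analytic gradients; fitting cost grows with the parameter count
  through finite differencing (39 parameters at the full covariate set is
  ~10 s at n ≈ 5000).
- No survey-design adjustment; estimates from DHS-style complex samples
  inherit that caveat.
- K = 2 components only; no model-based choice of K.
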