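# ancmix — marginalized Poisson–Poisson mixture regression for ANC visit counts

`ancmix` analyses counts of antenatal-care (ANC) visits — the number of
check-ups a woman receives during one pregnancy — when the population is a
mixture of two latent groups with different visit intensities. It is aimed
at epidemiologists and biostatisticians working with Demographic and Health
Survey (DHS)-style cohorts, where standard Poisson regression understates
the dispersion and plain mixture models do not yield population-wide effect
estimates.

## The model

Counts follow a two-component Poisson mixture

    f(y_i) = π · Pois(y_i; μ₁ᵢ) + (1 − π) · Pois(y_i; μ₂ᵢ),

with marginal mean and variance

    E(Y_i) = μ_i = π μ₁ᵢ + (1 − π) μ₂ᵢ,
    Var(Y_i) = μ_i + π(1 − π)(μ₁ᵢ − μ₂ᵢ)²  ≥  μ_i.

The *marginalized* parameterization substitutes
μ₂ᵢ = (μ_i − π μ₁ᵢ)/(1 − π) and models

    log μ_i = xᵢ′β,   log μ₁ᵢ = zᵢ′α,   logit(π) = τ,

so β acts directly on the population mean: exp(βⱼ) is the incidence density
ratio (IDR) — the multiplicative change in the average visit count per unit
change of covariate j, adjusted for the others. The likelihood is maximized
by quasi-Newton (BFGS, numerical gradients) from starting values built by an
EM fit of the latent-class mixture (for α, τ) and a marginalized
zero-inflated Poisson fit (for β); standard errors come from the numerically
differentiated observed information. Validity requires the implied
μ₂ᵢ > 0 on every row; outside that region the likelihood returns a smooth
penalty so the optimizer retreats.

Because the real cohort (BDHS 2017–18, n = 4941) is access-restricted, the
package ships a synthetic-cohort generator that reproduces its structure:
nine categorical covariates (study-continuity status, residence, media
exposure, mother's age at birth, spousal age difference, decision
participation, beating-justification count, wealth tertile, birth order)
sampled at the published marginal proportions, and counts drawn from the
mixture at the published coefficient values.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1   # synthetic cohort, n=4941
python analysis/02_describe.py                   # per-level means, ANOVA stars
python analysis/03_fit_models.py                 # mixture + baselines
python analysis/04_report.py                     # IDR table
python analysis/05_recovery_study.py             # Monte-Carlo calibration
```

With seed 1 the cohort has mean 3.85 visits (SD 2.90, range 0–19) — clearly
overdispersed — and the model comparison prints

```
     model        loglik  n_params          aic
   Poisson -12085.782992        19 24209.565983
    NegBin -11384.985993        20 22809.971986
MPois-Pois -11347.634571        39 22773.269143

best model by AIC: MPois-Pois
```

The mixture beats both baselines because the two latent components (fitted
mixing proportion π̂ = 0.586, SE 0.018) carry the extra variance that the
Poisson ignores and the negative binomial can only absorb through a generic
dispersion parameter. The report step then narrates the adjusted effects,
e.g.

```
study_continuity=not_continued_ge10: 10% lower (IDR 0.900)
study_continuity=drop_outed: 19.7% lower (IDR 0.803)
residence=urban: 10.2% higher (IDR 1.102)
```

— women who left school before reaching ten years of education average
about 20% fewer ANC visits than those who continued studying after
marriage, holding the other covariates fixed. The recovery study (100
replicates of n = 3000) confirms the estimator is calibrated: componentwise
|bias(β̂)| < 0.01, 95% Wald CI coverage 90–95%, and AIC prefers the mixture
on every overdispersed replicate.

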