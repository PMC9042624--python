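# plsfpm — PLS flexible parametric survival models

`plsfpm` fits survival models to data with many **collinear covariates** by a
two-stage procedure: (1) extract partial-least-squares (PLS) components of
the observed time from the covariate matrix, (2) fit fully **parametric
survival models** on those components by censored maximum likelihood. It is
aimed at epidemiologists and biostatisticians analysing survey-style survival
data (dozens of correlated predictors, modest n), where Cox regression on raw
covariates is unstable and its step-function baseline cannot extrapolate.

## The model

Let T be the survival time with right-censoring indicator e, and X the n×p
matrix of correlated predictors. Stage 1 runs univariate-response NIPALS:
for a = 1..A,

    w_a = X'_{a-1} y_{a-1} / ||X'_{a-1} y_{a-1}||      (loading weights)
    s_a = X_{a-1} w_a                                  (scores)

with X and y deflated by their regressions on s_a after each step. Stage 2
maximizes the right-censored likelihood

    ℓ = Σ_{e_i=1} log f(t_i) + Σ_{e_i=0} log S(t_i)

with the components entering the model linearly through the location
parameter of one of four baseline families:

| family            | parameters                  | components act on |
|-------------------|-----------------------------|-------------------|
| exponential       | rate λ                      | log λ (PH)        |
| Gompertz          | shape η, rate b             | log b (PH)        |
| generalized gamma | location μ, scale σ, shape κ| μ (AFT)           |
| generalized F     | location μ, scale σ, shapes s₁,s₂ | μ (AFT)     |

The Gompertz cumulative hazard is Λ(t) = (b/η)(e^{ηt}−1); the generalized
gamma uses the Prentice parameterization (κ=1 Weibull, κ=0 log-normal); the
generalized F satisfies e^{(log t−μ)/σ} ~ F(2s₁, 2s₂) and nests the
generalized gamma as s₂→∞. A PLS-Cox model (Breslow partial likelihood and
baseline) serves as the semiparametric reference, and models are compared by
AIC/BIC with held-out test log-likelihood from a seeded 70/30 split.
Component coefficients are back-projected to the covariate scale, where
their magnitudes drive **loading-weights factor selection**.

A simulator generates survival data with block-correlated predictors
(default: n=100, p=30, ten blocks with within-block correlations
0.9, 0.8, …, 0.1, 0 and a Gompertz(rate 0.1, shape 0.1) baseline) for
method validation.

## Worked example

```
$ python examples/02_two_stage_pipeline.py
simulated 100 subjects, 30 covariates, 100 events

model comparison (train AIC/BIC, held-out test log-likelihood):
     family  loglik  n_params    aic    bic  converged  test_loglik
   gompertz -174.55         4 357.10 366.09       True       -66.56
   gengamma -180.11         5 370.23 381.47       True       -67.57
       genf -180.11         6 372.23 385.72       True       -67.57
exponential -184.32         3 374.65 381.39       True       -68.69
        cox -198.24         2 400.48 404.97       True       -66.23

best family by AIC: gompertz

selected factors (truth: x1..x3 active, hazard-increasing):
factor  coefficient  statistic  selected  sign
    x1       -0.410      0.410      True    -1
    x2       -0.412      0.412      True    -1
    x3       -0.407      0.407      True    -1
```

The data were simulated from a Gompertz baseline, and the Gompertz family
wins the AIC comparison on the training 70%. The three covariates that truly
increase the hazard are exactly the selected factors; their negative
coefficients mean shorter survival (positive = longer survival, the AFT
convention). The generalized F reproduces the generalized-gamma fit because
its extra shape parameter collapses toward the nested case.

The same workflow is available from the shell:

```
plsfpm simulate --seed 7 --out sim.csv
plsfpm fit --input sim.csv --seed 7 --out results/
plsfpm compare results/ --out ranking.csv
```

Every `fit` run writes `comparison.csv`, `factors.csv`, `curves.csv`
(cumulative-hazard curves on a 0–12 grid per family) and a `manifest.json`
with the dataset hash and full configuration; identical seeds give
byte-identical outputs.

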