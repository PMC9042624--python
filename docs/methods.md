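# Methods

## Two-stage estimation

Stage 1 is univariate-response PLS (NIPALS/PLS1). The response is the
observed time by default (`response="logtime"` switches to log time); the
censoring indicator is ignored at this stage, so with heavy censoring the
extracted components target the *observed* rather than the latent event
time — users with substantial censoring should treat component choice and
selection results with corresponding caution. Covariates are centered and
scaled to unit variance by default (the method is intended for covariates on
heterogeneous scales); the response is centered only. Both X and y are
deflated after each component, the standard PLS1 recursion. Weight-vector
signs are fixed (largest-magnitude entry positive) so results are
reproducible across platforms and BLAS builds.

Stage 2 fits each family by full censored maximum likelihood with the A
component scores entering the location linearly: the log rate for
exponential and Gompertz (a proportional-hazards construction) and the
log-time location μ for generalized gamma and generalized F (accelerated
failure time). Ancillary scale/shape parameters carry no covariates, which
keeps the free-parameter counts at 1/2/3/4 plus A. Back-projection maps
component coefficients to the covariate scale through the standard PLS
rotation W(P'W)⁻¹, divided by the training scales; for the PH families the
sign is flipped in the report so that positive always means longer survival.

## Distributions

* **Gompertz** — hazard b·e^{ηt}, Λ(t) = (b/η)(e^{ηt}−1), computed with
  `expm1` so the η→0 (exponential) limit is exact. η < 0 makes the
  distribution improper (survival plateau e^{b/η}); fitting permits it, but
  `sample()` refuses unless `allow_improper=True`, returning `inf` draws the
  caller must censor — silent infinite samples would corrupt simulations.
* **Generalized gamma** — Prentice (μ, σ, κ): with w = (log t − μ)/σ and
  γ = κ⁻², γe^{κw} is Gamma(γ) for κ > 0 (upper tail for κ < 0, log-normal
  at κ = 0). Survival is a regularized incomplete gamma; κ=1 gives Weibull,
  κ=σ=1 exponential.
* **Generalized F** — the original four-parameter form: the density of
  w = (log t − μ)/σ is (s₁/s₂)^{s₁} e^{s₁w} (1+s₁e^w/s₂)^{−(s₁+s₂)} / B(s₁,s₂),
  equivalently e^w ~ F(2s₁, 2s₂), so the CDF/quantile use `scipy.stats.f`.
  As s₂→∞ it converges to the generalized gamma with κ = 1/√s₁,
  σ_gg = σ/√s₁ (verified numerically in the tests).

All likelihood evaluation is in log space; impossible parameter/observation
combinations return −∞ rather than raising, so optimizers can traverse bad
regions.

## Optimization and numerics

Quasi-Newton (BFGS) on transformed parameters (log for positive quantities)
with central-difference gradients (`jac="3-point"`; forward differences hit a
noise floor around 1e-8 in the parameters) followed by a tight Nelder–Mead
polish. Starts: the exponential MLE maps into each family through its nested
point (Gompertz at η≈0; generalized gamma at σ=κ=1 with negated
coefficients, since AFT location = −log rate for the exponential), the
generalized F starts from the generalized-gamma fit mapped to the s₂-large
nested point, plus two jittered restarts from a fixed internal seed. A fit
reports `converged=False` with diagnostics instead of a silent wrong answer;
convergence requires optimizer success or a scaled gradient-sup-norm
(‖g‖∞/(1+|ℓ|)) below 1e-5.

The Cox reference uses the Breslow partial likelihood (adequate for the
continuous simulated times; ties share the full risk set) with an analytic
gradient, and the Breslow baseline cumulative hazard for curve export.
AIC/BIC count only stage-2 parameters (A coefficients + free distribution
parameters); the PLS extraction is treated as a fixed transformation, so
criteria are comparable across families on the same scores.

Cumulative-hazard curves are exported on a 0–12 grid (step 0.1) at the
training-mean covariate profile; Gompertz grids that would overflow e^{ηt}
are clipped with a warning.

## Simulator

`SimulationConfig` defaults define the reference validation design: n = 100,
p = 30 standard-normal predictors in ten equal blocks with within-block
exchangeable correlations (0.9, 0.8, …, 0.1, 0) and independent blocks — the
simplest structure that consumes exactly that correlation ladder; an AR(1)
within-block option exists. The baseline is Gompertz with rate b = 0.1 and
shape η = 0.1. Effect sizes are sparse by default: the three covariates of
the first (most collinear, r = 0.9) block carry 0.5 on the log rate and the
rest are null — the regime PLS is designed for, and a known truth for
selection tests. Censoring is off by default, with administrative
(`("admin", 12)` mirrors a 12-month study window) and uniform schemes
available. Event times are inverse-CDF draws; for the PH families the
per-subject baseline cumulative hazard target E/e^{x'β} is inverted in
closed form to avoid precision loss near the uniform boundary.

What the simulator does *not* emulate: discrete/categorical covariates,
covariate measurement error, informative censoring, non-normal marginals,
time-varying effects. Passing tests therefore demonstrate correctness of the
estimation machinery under a known generating process, not robustness to
those real-data features.

## Factor selection

The selection statistic is the absolute back-projected coefficient (default)
or the absolute component-1 loading weight. No canonical cutoff exists for
loading-weights filtering, so two rules are exposed: relative
(|stat| ≥ c·max|stat|, default c = 0.5) and absolute (|stat| ≥ c, a value
near 0.1 is sensible for standardized survey covariates). Both are
assumptions, not estimates; `stability_check` quantifies how sensitive the
selected set is to the random 70/30 split. Reported signs follow the AFT
convention (positive = longer survival); hazard-scale signs are opposite.

## Problem sizes and defaults used in validation

The validation study (tests and `scripts/acceptance.py`) uses: 50 replicates
of the default design for family identification by AIC; 20 seeds at n = 2000
for intercept-only Gompertz recovery (median relative error of both
parameters is ~3%, comfortably under the 10% criterion); 20 replicates for
selection power (all three actives in the top five statistics); A = 2
components throughout, a deliberate default for n = 100 — `n_components="auto"`
selects A by 5-fold cross-validated stage-2 exponential log-likelihood on a
1..min(10, p) grid when wanted.

## Known limitations

* Stage-1 PLS ignores censoring (see above) — acceptable at the default
  censoring levels, increasingly biased as censoring grows.
* Generalized F fits are weakly identified when the data do not distinguish
  it from its generalized-gamma subfamily; the optimizer then returns the
  nested fit (identical log-likelihood, one extra parameter in the
  penalties), which is the honest answer.
* No left truncation or interval censoring; no spline-based baselines;
  single-response PLS only.
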