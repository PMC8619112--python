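# Methods

## Model

For subject i in arm j of a g-arm randomized trial (arm g is the control),
with binary outcome Y_ij and covariate vector x_ij:

```
logit π_ij = (μ + τ_j + x_ij'β)(1 + δ_j),    π_ij = P(Y_ij = 1 | x_ij)
```

τ = (τ₁,…,τ_{g−1}) are additive (absolute) treatment effects in log-odds
units; δ = (δ₁,…,δ_{g−1}) are dimensionless relative effects, each
constrained to (−1, 1) so that the multiplier 1+δ_j stays positive.  The
full parameter vector is θ = (μ, τ', β', δ')', of length 2g+p−1.  Setting
δ = 0 recovers ordinary logistic regression exactly, so the model nests its
classical special case and any fitted enhanced model has log-likelihood at
least as high as the δ=0 fit on the same data.

Two indicator codings are supported and must be chosen explicitly:

* **baseline** — control arm carries τ = δ = 0; indicators are 0/1.
* **sum-to-zero** (two arms only) — τ₂ = −τ₁, δ₂ = −δ₁ with ±1 indicators.
  Under this coding the relative change in log-odds between arms (without
  an absolute effect) is 2δ₁/(1−δ₁), not δ₁ itself; the helper
  `constrained_relative_change` computes it.

Interaction columns (treatment indicator × base covariate) are expanded
into the covariate matrix at data-construction time and *flagged* with the
treatment they multiply.  Under sum-to-zero coding the indicator is ±1, so
the interaction contribution flips sign with the arm; effect measures fold
the flagged coefficient in with the arm-appropriate sign.  Explicit
expansion was chosen over formula-style implicit interactions because the
two codings give different column values and silent mismatches would
corrupt every downstream effect measure.

## Effect measures

* **Within-arm**: per unit of covariate k in arm j the log-odds change by
  (β_k + c_j γ_k)(1 + δ_eff(j)), where γ_k is the flagged interaction
  coefficient (0 if none), c_j the coded indicator and δ_eff(j) the coded
  relative effect of the arm.  `scale="odds"` exponentiates.
* **Between-arm**: the log-odds difference between two arms at a fixed
  covariate profile, with interaction columns recomputed per arm.  Under
  baseline coding against the control this reduces to
  τ_j + (μ + τ_j + x'β)δ_j.  `effects_report` tabulates the exponentiated
  version over a covariate grid (with optional per-covariate transforms,
  e.g. reciprocal weight) and `odds_ratio_ranges` collapses it to min–max
  ranges per stratum, the presentation used in trial reports.

## Estimation

The log-likelihood is l(θ) = Σ y·lp − log(1+e^lp) with lp = m·(v'β*),
v = (1, T', x')', β* = (μ, τ', β')', m = 1 + R'δ.  The score is analytic;
writing a = v'β*, r = y − π, w = π(1−π), the observed-information blocks
are

```
∂²l/∂β*∂β*' = −Σ w m² v v'
∂²l/∂δ ∂δ'  = −Σ w a² R R'
∂²l/∂β*∂δ'  =  Σ (r − w·m·a) v R'
```

The cross block carries a first-order residual term in addition to the
usual weighted outer product because the linear predictor is a *product*
of the two parameter blocks.  Both derivatives are verified against
central finite differences in the test suite.

Fitting strategies:

* **Profile grid (two arms, default).** δ₁ is profiled on an equally
  spaced grid of 201 points over [−0.99, 0.99] (endpoints pulled in from
  ±1 to keep 1+δ strictly positive).  At each grid value the model in
  β* is an ordinary logistic regression on the m-scaled design, maximized
  by damped Newton and warm-started from the previous grid point.  The
  grid argmax (ties broken toward smaller |δ₁|) is then polished by one
  full Newton run, removing grid-resolution bias; the profiled trace is
  retained for diagnostics.  Grid fits that fail are skipped with a
  warning; the fit errors only if every grid point fails.
* **Full Newton (g > 2, or on request).** Joint Newton–Raphson over all
  free parameters, started at the δ=0 logistic fit.  By default iterations
  run in the reparameterization δ_j = (e^{η_j}−1)/(e^{η_j}+1), which maps
  the real line onto (−1,1) so δ can never leave its domain; the gradient
  and Hessian are chain-ruled through dδ/dη = (1−δ²)/2.

Step control: a raw Newton step that would decrease the log-likelihood is
halved up to 20 times; a singular Hessian receives an escalating ridge
(1e−8 up to 1e−2) before the step is abandoned.  Convergence is declared
when the max-norm of the score (δ scale) drops below 1e−8 or an accepted
full step improves the log-likelihood by less than 1e−10; hitting the
iteration cap returns a result flagged `converged=False`.  Fitted
log-odds exceeding 30 in magnitude raise a separation warning, since the
MLE diverges under perfect separation.

`fix_mu_zero` fits without an intercept (μ pinned at 0 but kept in the
parameter layout so one Theta shape serves all models); `fix_delta_zero`
gives the ordinary-logistic comparator through the same Newton machinery.

## Inference

Standard errors are sqrt of the diagonal of the inverse *observed*
information (negative Hessian at θ̂) on the original δ scale, with Wald
z-statistics, two-sided normal p-values and estimate ± z·SE intervals.
Observed information is used because it is available exactly for any
coding and sample; the test suite checks it against a nonparametric
bootstrap.  A non-invertible information matrix yields NaN standard errors
plus a warning, and `wald_inference` then raises with advice to refit
under the η reparameterization or reduce the model.

## Synthetic-data generator and reproduction studies

`generate_dataset` draws covariates i.i.d. per column spec (standard
normal, or Bernoulli with probability 0.5 by default), splits subjects
equally between arms (deterministic counts), expands interaction columns
under the coding in force, and samples Y ~ Bernoulli(π) with π from the
generative model at the true parameters.  Everything flows through one
`numpy.random.Generator`, so a fixed seed gives bit-identical trials.

Two benchmark designs, used as the package's reference study conditions:

* `benchmark_design(n, delta1)` — baseline coding, four N(0,1) covariates,
  β0 = (−0.5, 0.5, −0.5, 0.5), τ1,0 = −1, μ0 = 0;
* `benchmark_interaction_design(n, delta1)` — sum-to-zero coding, two
  N(0,1) covariates plus interactions t₁x₁ and t₁x₂, same β0 and τ1,0.

μ0 defaults to 0 (configurable).  Because the generative intercept is 0,
the reproduction studies fit *both* models without an intercept
(`fix_mu_zero=True`); with a free intercept the logistic comparator's
treatment-effect SE grows from ≈0.10 to ≈0.14 at n=1000 and its coverage
collapse is correspondingly milder (≈0.57 rather than ≈0.27).

`mc_study` fits the enhanced model (profile grid) and the logistic
comparator to each replicate and reports mean estimate, SD of estimates,
mean model-based SE and empirical coverage of nominal 95% Wald intervals.
For the logistic fit the coverage target for the treatment coefficient is
the generative τ1,0 — deliberately, since the question is whether the
misspecified model covers the true absolute effect.  Replicates whose fit
does not converge or whose information matrix is not invertible are
dropped from that model's summaries and counted; a warning is recorded if
more than 10% drop.

`classification_study` redraws the true model each replicate (β uniform on
(−2.5, 2.5), τ1,0 uniform on (0, 2), δ1,0 uniform on a chosen range,
sum-to-zero coding; covariates x₁, x₂ N(0,1), x₃ Bernoulli(0.5),
interaction t₁x₁, n=1000) and reports paired in-sample sensitivity and
specificity at probability threshold 0.5.  Metrics are in-sample: the
comparison targets representational adequacy of the two models on the same
data, not out-of-sample generalization.

### Problem sizes

The test suite runs 600 Monte-Carlo replicates per estimation design
(tolerances stated for 1000-replicate summaries are widened by
√(1000/600)) and 300 replicates per classification range, with a 41-point
profile grid plus Newton polish; `scripts/acceptance.py` uses 1000
replicates per design.  These sizes give Monte-Carlo standard errors of
roughly 0.003–0.006 on mean estimates and ≈0.015 on coverage
probabilities.

## What the synthetic studies do and do not show

The generator emulates the idealized trial of the benchmark designs:
independent homoscedastic covariates, exact Bernoulli outcomes from the
assumed link, equal allocation, no missingness, no measurement error, no
unmeasured confounding.  Passing reproduction tests therefore demonstrates
the correctness of the estimator and the predicted failure mode of the
misspecified logistic fit under these conditions — not that real trials
follow the enhanced model.  Real-data effect measures in the examples are
computed from published, 3-dp-rounded coefficient tables, so they
reproduce printed arithmetic rather than refit raw data (which is not
packaged).

## Known limitations

* δ̂ near ±1 (severe relative effects or quasi-separated data) makes the
  observed information ill-conditioned; such replicates are flagged and,
  in Monte-Carlo summaries, dropped.
* Sum-to-zero coding is defined for two arms only; g > 2 requires baseline
  coding and full-Newton fitting, and the Monte-Carlo harness itself is
  two-arm.
* Only Wald inference is provided (no likelihood-ratio or profile-CI
  machinery); no penalized estimation for high-dimensional covariates;
  binary outcomes only.
* Relabelling which arm is control is an exact reparameterization only
  when the remapped δ' = −δ/(1+δ) stays inside (−1, 1), i.e. δ > −1/2.
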