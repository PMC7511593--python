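# Methods

## The model

`modmedsem` works with the second-stage moderated mediation model for latent
variables.  Four latent constructs — a predictor X, a mediator M, a moderator
Z and an outcome Y — follow the structural equations

    M = a·X + δ_M
    Y = c·X + b1·M + b2·Z + b3·(M·Z) + δ_Y ,

where (X, Z) are jointly Gaussian and the M·Z product makes the M→Y path
conditional on the moderator.  Each construct is measured by a congeneric
indicator block (`x1–x3`, `m1–m4`, `z1–z3`, `y1–y4`),

    v_j = τ_j + λ_j·(construct) + δ_j ,

with the first loading of every block fixed at 1 for scale.  The quantities of
applied interest are the interaction slope `b3`, the moderated-mediation index
`a·b3`, and the conditional indirect effects `a·(b1 + b3·z)` at moderator
values z ∈ {−1 SD, 0, +1 SD}.

## The population generator

`popgen.make_population_spec` fixes the data-generating parameter values used
throughout: loadings λ_X = (1, .65, .72), λ_M = (1, .81, .53, .66),
λ_Z = (1, .83, .79), λ_Y = (1, .68, .75, .83); all intercepts 0.5; paths
a = .75, b1 = .56, b2 = .48, c = .3 with b3 ∈ {0, .2, .4} by design cell;
unit latent variances, Cov(X,Z) ∈ {0, .3}, structural residual variances
0.36.  Reliability is manipulated through the indicator error variances:
0.36 (block reliabilities ≈ .82–.90, "high") versus 1.5 (≈ .54–.68, "low").
The closed-form population Cronbach's alphas under these settings are
0.823/0.837/0.859/0.896 (high) and 0.545/0.570/0.601/0.685 (low) for
X/M/Z/Y, and `popgen.population_alpha` exposes them as an oracle.

Measurement errors come in five flavors (`sample_error`): normal; U[0,1]
centered to mean zero with its natural variance 1/12; two symmetric
heavy-tailed constructions z/√(χ²_df/(df−2)) with df = 5 (moderate kurtosis)
and df = 4.5 (high kurtosis, configurable), both rescaled to the cell's error
variance; and χ²(1) centered to mean zero with its natural variance 2
(skewness √8).  The printed sources for the two heavy-tailed types are
typographically ambiguous; the normal-over-scaled-chi-square form is the
standard construction in the simulation literature they belong to, df of the
high-kurtosis divisor is exposed as an argument, and both keep unit variance
before rescaling.  The uniform and χ²(1) types deliberately keep their
natural variances (a `rescale_natural` flag restores the cell's variance):
rescaling would preserve shape but silently undo the reliability
manipulation these types are meant to stress.  Non-normal errors apply to
the M- and Z-block indicators only; X- and Y-block errors stay normal.

For normal errors, `population_moments` returns the exact implied mean and
covariance of the 14 indicators.  The latent product M·Z has mean
Cov(M,Z) = a·Cov(X,Z), variance Var(M)Var(Z) + Cov(M,Z)², and zero
covariance with X, M and Z because odd central moments of Gaussians vanish;
those identities are what the closed form (and the CPI constraints below)
rely on, which is why the oracle refuses non-normal error types.

Randomness is handled with one master seed per run; every (cell, replication)
pair gets its own `numpy` child generator via
`rng_for(master_seed, cell_index, rep_index)`, so any cell is reproducible in
isolation and results do not depend on execution order.

## What the generator does *not* emulate

Generated data are ideal in ways real scale data are not: no missingness, no
categorical/floor-ceiling effects, exact simple structure (no cross-loadings
or correlated errors), and within-block equal error variances.  Passing tests
therefore demonstrate estimator behavior under the stated population models,
not robustness to the messiness of applied data.

## The four estimators

**PA** (`estimators_pa`): block means replace the latents and the two
structural equations are fitted by least squares.  Because composite scores
carry measurement error, every path is attenuated; the asymptotic bias of the
interaction slope is ≈ −8.5% at reliabilities near .8 and ≈ −57% near .6, and
the indirect effect is ≈ −27% biased even at high reliability.  Mc and Zc are
mean-centered before forming the product by default — this only
reparameterizes lower-order terms, and a flag restores the raw product.  PA
always completes (least squares on a full-rank design cannot fail to
converge).

**CPI / UPI** (`estimators_pi` on top of `sem_core`): the latent interaction
gets indicators built as products of M- and Z-indicators.  Indicators are
paired by descending estimated loading ("matching": rank-to-rank, ties by
original order, leftovers unproducted); loadings are estimated by a
covariance-ratio moment method so the estimator only ever sees data.  Paired
indicator columns are mean-centered before multiplying, which places the
latent-mean constraint E(MZ) = a·Cov(X,Z) on the centered metric with product
intercepts fixed at 0.  CPI additionally derives each product loading
(λ_m·λ_z), each product error variance
(λ_m²·Var(M)·θ_z + λ_z²·Var(Z)·θ_m + θ_m·θ_z), Var(MZ) and the
MZ-covariances (zero, by Gaussian moment identities) from the base free
parameters; UPI frees all of those except the latent mean (one product
loading fixed for scale, Cov(MZ,X) and Cov(MZ,Z) free), costing 8 extra
parameters.

`sem_core.ml_fit` minimizes the normal-theory discrepancy
F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p + (x̄−μ)'Σ⁻¹(x̄−μ) with L-BFGS-B.
The gradient is assembled from the analytic derivatives of F w.r.t. (μ, Σ)
chained with central-difference Jacobians of the data-free moment map — the
map costs microseconds, so this is effectively an analytic gradient at finite-
difference prices.  Convergence requires a gradient infinity-norm below 1e-6
(up to two optimizer restarts absorb premature line-search stops); a solution
is *proper* when, additionally, every variance-type estimate is non-negative
and the implied covariance at the optimum is positive definite.  Variances are
deliberately optimized unbounded so that Heywood cases surface as improper
solutions (bounding them at zero would hide exactly the completion-rate
behavior the simulation study measures).

**LMS** (`estimators_lms`): no product indicators.  Conditional on Z = z the
model is linear-Gaussian — X|Z=z is Gaussian through Cov(X,Z), and Y's
equation has slope b1 + b3·z on M — so the marginal likelihood is the
integral over z of a Gaussian density, approximated by Gauss–Hermite
quadrature as a K-component Gaussian mixture with node-specific (μ_k, Σ_k).
Only the moderator needs integrating: conditional on Z everything else is
jointly Gaussian, so the quadrature is one-dimensional regardless of model
size.

Numerics that matter:

* *Gradients and scores.* The mixture log-likelihood's derivatives w.r.t.
  (μ_k, Σ_k) are analytic (responsibility-weighted Gaussian identities);
  they are chained with batched central-difference Jacobians of the cheap
  map θ → (μ_k, Σ_k).  This yields the total gradient at ~2 likelihood
  evaluations' cost and per-case score vectors for free, which is what makes
  replicated simulation with robust SEs feasible (≈ 0.5 s per fit at
  n = 500, K = 16 on one core).
* *Quadrature order.* K = 16 is the default.  The prior-scaled
  (non-adaptive) rule converges slowly in the log-likelihood *value* because
  each case's posterior over z is ~3× narrower than the prior — the value
  error at K = 16 is ~1e-2 per case, vanishing by K ≈ 128 — but parameter
  estimates are insensitive (b̂3 moves < 1e-3 going to K = 48, far below
  Monte-Carlo error).  Likelihood-value comparisons (oracle tests, reported
  log-likelihoods for LR tests at tight tolerances) should use K ≥ 64;
  `LmsModel(K=...)` and the `K` argument expose this everywhere.
* *Robust SEs.* `robust_se` computes the sandwich A⁻¹BA⁻¹ with A the
  numerical Hessian of the negative log-likelihood (central differences of
  the analytic gradient, step 1e-5 relative) and B the sum of per-case score
  outer products.  Under a correctly specified model the two SE flavors
  (`robust`, `hessian`) agree, which is tested.
* *Inadmissible points* (non-PD Σ_k, negative Var(Z), negative conditional
  Var(X|Z)) return a large penalty with a zero gradient; L-BFGS-B's line
  search backtracks out.
* *Start values* come from block-wise moment CFA estimates plus the
  composite-regression paths — attenuated but in the right region, roughly
  halving iteration counts relative to generic starts.

Model-fit comparison follows the two-step logic: fit the model with b3 fixed
at zero (Model 0), fit the interaction model, and compare with the
likelihood-ratio statistic −2(ℓ0 − ℓ1) on 1 df (`lr_model_comparison`; a
materially negative statistic is flagged as an optimizer-failure warning and
truncated at 0).  `johnson_neyman` traces the simple slope b1 + b3·z with its
pointwise 95% normal-theory band and reports where it excludes zero;
`jn_crossover_points` solves the band's boundary quadratic in closed form.

Derived effects use each estimator's own moderator scale: PA evaluates ±1 SD
at the sample SD of the composite Zc, CPI/UPI/LMS at the model-estimated
√Var(Z) — each method can only see its own metric.  Delta-method SEs for
a·b3 and a·(b1+b3z) treat z as fixed.

## Inference

`uncertainty.bootstrap` is a case-resampling bootstrap (default B = 100
draws, the smallest defensible number and the one the simulation design
uses): SE = SD over draws, CI = outward-rounded 2.5/97.5 percentile order
statistics.  Draws where the estimator fails to produce a proper solution are
counted in `n_failed` and excluded rather than redrawn, keeping B
interpretable.  Significance decisions use the two-sided normal-theory Wald
test at α = .05 with whichever SE flavor the condition specifies (robust for
LMS by default); CI-exclusion decisions can be computed side by side.

## The simulation studies and metrics

`simstudy.run_cell` generates data and runs any subset of the estimators per
replication, recording estimates, SEs, Wald p-values and 95% CIs for b3, the
index and the three conditional indirect effects, plus convergence/properness
flags; estimator exceptions are logged as non-complete replications and never
abort a cell.  `study1_cells()` is the 4 (N ∈ {100, 200, 500, 1000}) ×
3 (b3 ∈ {0, .2, .4}) × 2 (reliability) grid; `study2_cells()` crosses the
five error distributions with Cov(X,Z) ∈ {0, .3} and b3 ∈ {0, .2} at N = 200.

Per (cell × estimator × parameter), `summarize` reports

* relative bias (mean estimate − truth)/truth, with raw mean bias
  (flagged) where the truth is zero since relative bias is undefined there;
* SE ratio mean(SE)/SD(estimates) (n−1 SD), calibration window [0.9, 1.1];
* coverage of the closed 95% interval, acceptability > 0.90;
* rejection rate of the Wald test — power for non-zero truth, type-I error
  (binomial window [0.0365, 0.0635] at 1,000 replications) for zero truth;
* completion rate = proper solutions / replications.

Accuracy metrics are computed over proper-solution replications only, with
completion reported separately; an averaged "ind" block takes the mean of
each metric over the three moderator values.  Truths use the population
moderator SD (√Var(Z) = 1).

## Problem sizes

The package's working profile is desk-scale: 100 generated datasets for
reliability summaries, 200 replications per cell for PA-based bias
quantities, 100–200 replications for LMS rejection rates, bootstrap B = 100.
At these sizes the binomial/Monte-Carlo error is a few percent, which is the
resolution at which the full-scale (1,000-replication) results are quoted;
the full grid remains available through `run_cell`/the CLI by raising
`reps`.

## Known limitations

* The normal-theory closed-form oracle (and hence the CPI constraints) is
  exact only under normal errors; under types 2–5 CPI is deliberately
  misspecified — that misspecification is the object of study, not a bug.
* LMS integrates over a single moderating latent; models with several
  distinct latent interactions would need a product rule.
* Bayesian estimation, parceling strategies, missing or categorical data are
  out of scope.
* Completion ("fully proper") rates depend on the properness definition
  (converged + non-negative variances + PD implied covariance); software
  with different conventions (e.g. bounded variances) will report different
  absolute rates, though orderings across estimators are stable.
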