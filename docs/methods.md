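# Methods

This note documents the statistical machinery implemented in `bloqreg`: the
observation model for values below a lower limit of quantification (LLOQ),
the eight handling methods, the synthetic data-generating process used to
compare them, the performance metrics, and the numerical and design choices
made where the procedure was genuinely open.

## Observation model

A left-censored variable is observed as

    x_obs = x        if x > LLOQ
    "< LLOQ"         if x <= LLOQ

with a known, constant threshold `LLOQ > 0`. Ties (`x == LLOQ`) are treated
as censored. Internally (`CensoredVector`) censored slots store the sentinel
value `LLOQ` — never NaN — together with a boolean flag vector; consumers
must branch on the flag, not the value. Uncensored values are required to
lie strictly above the threshold. Right censoring, interval censoring and
time-varying limits are out of scope.

## Handling methods

**Discard** fits OLS on the uncensored rows. When the BLOQ variable is a
regressor this is exactly unbiased (selection on a covariate), at the cost
of efficiency; when it is the outcome it selects on the response and is
biased.

**Substitution** replaces every censored slot with a constant: 0, LLOQ,
LLOQ/2 (the conditional mean if values below the limit were uniform) or
LLOQ/√2. The last is the point `l` splitting the mass of a triangular
density `f(x) ∝ x` on (0, LLOQ) in half, i.e. the solution of
`∫_l^L c·x dx = ½ ∫_0^L c·x dx`.

**Tobit** treats a censored *outcome* by maximum likelihood: with
`y* = xᵀβ + ε`, `ε ~ N(0, σ²)` observed only above `c = LLOQ`,

    log L(β, σ) = Σ_unc [ log φ((yᵢ − xᵢᵀβ)/σ) − log σ ]
                + Σ_cens log Φ((c − xᵢᵀβ)/σ).

The optimiser works in (β, log σ) so the scale stays positive, starts from
the OLS fit with censored outcomes held at the sentinel, and uses BFGS with
the analytic gradient (the censored score involves the inverse Mills ratio
φ/Φ, evaluated via log-differences for tail stability). Standard errors
come from the inverse of the numerically evaluated Hessian of the negative
log-likelihood at the optimum; intervals are Wald with the normal 0.975
quantile. A stationary point that scipy labels "precision loss" but whose
scaled gradient is below 1e-5 is accepted as converged. The implementation
agrees with R's `survival::survreg` (left-censored gaussian) to ~1e-9 on a
frozen test dataset, and collapses exactly to OLS when nothing is censored.

**k nearest neighbours** imputes each censored slot with the mean of the
`k = 5` nearest uncensored donors, where distance is Euclidean on z-scored
covariates (standardised over the full table; all observed *independent*
variables, never the response). Because donors are by definition above the
limit, the donor mean always exceeds the LLOQ; capping it at the limit
(`truncate_at_lloq=True`) would make kNN numerically identical to LLOQ
substitution whenever flags come from thresholding, so the cap is off by
default and exposed only as an option. With fewer than `k` donors all
donors are used and a warning is recorded.

**KDE imputation** estimates a single value `k = E(X | X < LLOQ)` from a
Gaussian-kernel density and imputes it into every censored slot. The
bandwidth is Silverman's rule `h = 1.06 · sd(observed) · m^(−1/5)` with `m`
the number of uncensored values, computed once from the observed sample.
(A variant with the exponent `+1/5` — a form sometimes printed in the
literature, under which the bandwidth grows without bound — is exposed via
`bandwidth_exponent` but is not the default; likewise the kernel
normalisation constant is the standard `1/√(2π)`, which in any case cancels
in the conditional-mean ratio.) The conditional mean is computed by
trapezoid integration of `x·f̂(x)` against `f̂(x)` on 2048 equally spaced
points spanning `(max(0, min(observed) − 3h), LLOQ]` — the lower bound is
floored at 0 because the BLOQ variables handled here are non-negative. The
density is then re-estimated from the observed values plus one copy of the
current iterate per censored slot ("refit" augmentation; an alternative
"append" scheme adds one copy of every past iterate) and the process
repeats until `|k_j − k_{j−1}| < 10⁻⁵` (configurable), up to 500
iterations. Failure to converge raises an error carrying the iterate
trace; an empty integration interval or vanishing mass below the limit
raises "no mass below LLOQ". The returned value is strictly below the
limit and the procedure is fully deterministic.

**Two-compartment model** splits a censored *regressor* into
`x_bin = 1{x ≤ LLOQ}` and `x_cont = x` (uncensored) or a fill constant in
`[0, LLOQ]` (censored; default 0), entering both as regressors. The
coefficient on `x_cont` — the effect of interest — is invariant to the fill
because changing it only shifts the indicator's coefficient. When a dataset
happens to contain no censored rows the constant indicator column is
dropped before fitting to avoid rank deficiency.

All OLS-type fits report t-based 95% confidence intervals through
statsmodels; the applicability matrix (tobit: dependent role only,
two-compartment: independent role only) is enforced before any computation.

## Synthetic data generator

Two generating mechanisms drive the comparison:

* **Model 1** (BLOQ regressor): `y = 40 + 3·age − 1.5·sexmale + 5·crp + ε`
  with `age ~ N(53, 4.17)` (the second parameter is read as the standard
  deviation; a `normal_interpretation="variance"` switch exposes the other
  reading), `sexmale ~ Bernoulli(0.6)`, `crp ~ Beta(a, b)`,
  `ε ~ N(0, σ)`. The non-linear variant replaces the CRP part with
  `3·crp + crp²`.
* **Model 2** (BLOQ outcome): `y = 2·treat − 0.5·x1 + 3·x2 + ε` with
  `treat ~ Bernoulli(0.6)`, `x1 ~ N(2, 2)`, `x2 ~ Beta(a, b)`. No intercept
  is generated, but fitted models always include one.

Five settings: S1/S4/S5 use the right-skew-labelled Beta(8,2), S2 the
left-skewed Beta(2,8), S3 the centered Beta(5,5); S4 adds a correlation
(crp–age 0.8 in Model 1, treat–x1 0.6 in Model 2); S5 (Model 1 only) adds
the quadratic term.

**Noise calibration.** σ is chosen so the correctly specified linear fit
attains a target adjusted R² (0.6 or 0.1) on a 100,000-row population:
with `R² = Var(η)/(Var(η) + σ²)` for the linear predictor η,
`σ = sqrt(Var̂(η)·(1−R²)/R²)`, with Var̂(η) estimated on one seeded
population draw. At this population size the adjustment for model degrees
of freedom is negligible; a verification fit on a fresh population lands
within ±0.01 of the target.

**Correlation injection.** S4 couples the two margins through a Gaussian
copula: a latent bivariate normal with correlation ρ_z is transformed
through the probability-integral maps of the two margins, so the margins
are exact by construction. ρ_z is calibrated by monotone bisection on a
seeded 10⁶-draw pilot (common random numbers across bisection steps) until
the observed-scale Pearson correlation is within 0.005 of target; targets
beyond the attainable (Fréchet-type) bound for the margin pair raise an
error. The calibrated value is cached. Whether the study's correlation is
meant on the observed or a latent scale is not stated; the observed-scale
Pearson target is used.

**Censoring thresholds.** A scenario's LLOQ is fixed across replicates at
the *theoretical* quantile of the BLOQ variable's distribution, so the
censoring proportion holds in expectation rather than being enforced
exactly per replicate (avoiding replicate-dependent thresholds). For
Model 2 the outcome has no closed-form quantile; a dedicated seeded
10⁶-draw Monte-Carlo quantile is computed once per scenario and cached.
Because the Model-2 outcome has substantial mass below zero, very low
censoring proportions can imply a non-positive threshold; such scenarios
raise an informative error rather than a meaningless limit (left-skewed
S2 at R² = 0.6 needs a proportion of roughly 0.35 before the threshold
turns positive).

**Seeding.** Every scenario derives independent, individually re-runnable
streams from its root seed via `numpy` `SeedSequence` spawn keys (one
stream per replicate, plus dedicated streams for calibration, thresholds
and populations). Scenario output is a pure function of (config, seed);
the CLI writes a manifest (config hash, seed, per-scenario σ and LLOQ,
package version) sufficient to regenerate results bit-identically.

## Performance evaluation

For each (scenario, method) cell, with the tracked coefficient β (CRP in
Model 1 — the `x_cont` coefficient for the two-compartment fit — and the
treatment effect in Model 2):

* **bias** = mean(β̂) − β, with Monte-Carlo SE sd(β̂)/√r;
* **coverage** = fraction of replicates whose 95% interval contains β,
  with MC-SE sqrt(p(1−p)/r);
* **population MSE** (Model 1 only) = mean squared prediction error over a
  100,000-row population whose CRP is censored at the scenario LLOQ and
  completed with the rule the method learned at training time: the
  substitution constant, the training KDE value, the training kNN donor
  pool (population covariates standardised with training moments), or the
  two-compartment fill; for discard — which learns no completion rule —
  the sentinel LLOQ is used. A `censor_population=False` flag evaluates
  against the clean covariate instead. This population-side completion is
  a design choice of this package; it mainly affects the discard and kNN
  curves, and rankings among those methods at low censoring proportions
  are sensitive to it (differences there are a fraction of a percent of
  the total MSE).

Under the quadratic mechanism (S5) the misspecified linear model has no
single true CRP coefficient; the pseudo-true value is defined as the CRP
coefficient of the linear model fitted to the 100,000-row population. For
a convex increasing CRP contribution on (0,1) this projection exceeds the
linear part's coefficient.

Non-converged or failed replicate fits are excluded from metric numerators
and denominators but tallied (`reps_effective`, plus a failure ledger), so
successful + failed replicates always equals the configured count; a
scenario never aborts because individual replicates fail (e.g. too few
uncensored rows at 95% censoring with n = 30).

## What the generator does and does not emulate

The generator reproduces the covariate laws, effect sizes, noise
calibration, censoring mechanism and correlation structure stated above —
the conditions under which the method comparison is defined. It does not
emulate features of real laboratory data such as skewed measurement error,
multiple simultaneously censored variables, time-varying detection limits,
covariate missingness, or model misspecification beyond the single
quadratic term. Passing tests therefore demonstrate correctness of the
methods and the stated rankings *under these conditions*, not performance
guarantees on arbitrary real datasets.

## Numerical choices and degenerate inputs

* Tie-break: `value == LLOQ` is censored everywhere.
* kNN distance ties are broken by row order (stable neighbour search).
* Tobit with zero censored rows equals OLS to optimiser tolerance (the
  MLE scale uses n, not n − p); with all rows censored the likelihood is
  unidentified and an error is raised.
* KDE needs at least two uncensored values (bandwidth) and one censored
  slot; a degenerate zero-variance observed sample is rejected.
* Discard requires at least p + 2 uncensored rows for p coefficients.
* OLS design matrices always carry an explicit intercept; the
  two-compartment indicator is dropped only when constant.

## Known limitations

* Single BLOQ variable per dataset; one constant threshold.
* The restricted formula grammar supports additive main effects only.
* The population-MSE completion convention is one of several defensible
  readings (see above); both variants are computable but rankings among
  near-tied methods at low censoring depend on it.
* Desk-scale defaults (reduced grid, 200 replicates) trade Monte-Carlo
  resolution for runtime; the full grid (9 sample sizes, 20 proportions,
  1000 replicates, both R² targets) is available behind `--full-grid` and
  is hours-scale.
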