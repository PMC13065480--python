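# Methods

This note documents the statistical models the package implements, the
estimation machinery, the synthetic data the validation rests on, and the
design decisions taken where more than one reasonable choice existed.

## Data model

The analysis unit is the **person-year**: one individual, one calendar
year, a binary vector of adverse-life-event indicators (or a single yearly
count for count-only simulations), the individual's household for that
year, and age.  A household is a *specific set of co-residents*: any
member entering or leaving creates a new household id, so household ids
are crossed, not nested, with individual ids.  "Consecutive" observation
means calendar year t+1 following year t exactly; when an individual has
several qualifying runs of a requested window length, the earliest is
kept (deterministic, reproducible).  Missing event cells are parsed from
`NA`/empty CSV tokens into an audit mask; imputing missing-as-zero keeps
the mask so the imputation rate remains reportable.  Exclusivity
violations in input data (two members of a mutually exclusive event group
both 1 in a person-year) are hard errors rather than silent fixes, since
the emulated instruments preclude them by design.

Two catalog presets emulate the instruments of large national household
panels: a Swiss-style catalog (12 events, 7 of which are mutually
exclusive illness/accident subcategories, hence k = 12 − 6 = 6
independent event slots per year) and an Australian-style catalog (13
independent events, k = 13).  Their per-event base rates (0.1%–15% per
person-year) are descriptive defaults in the generator, chosen to span
the frequency range such instruments report.

The cumulative-count descriptives report two dispersion statistics under
unambiguous names — `sd_over_mean` (classical coefficient of variation)
and `variance_over_mean` (index of dispersion) — because the two are
easily conflated in applied summaries and only the latter can exceed ~2
for counts bounded by 20·k.

## Estimation: crossed-random-intercepts GLMM via Laplace

Families: Poisson (log link), binomial (logit), beta-binomial (logit on
the mean μ, log link on the dispersion φ, Morris parameterization with
count variance μ(1−μ)·n(φ+n)/(φ+1); Beta shapes α = μφ, β = (1−μ)φ).

The marginal likelihood integrates two crossed random-intercept vectors
(individual, household) out of the joint likelihood.  Adaptive per-group
quadrature is unavailable for crossed designs, so the integral is
Laplace-approximated:

1. **Inner step** — damped Newton on the joint penalized log-likelihood
   over (β, u, v), using sparse assembly of the bordered Hessian and a
   sparse LU solve; a 1e−8 ridge on the fixed-effect block guards
   collinear columns.  Convergence at max-gradient 1e−9·(1+|f|).
2. **Laplace value** — joint log-likelihood at the mode minus half the
   log-determinant of the random-effect block of the negative Hessian,
   minus the Gaussian normalization.
3. **Outer optimization** — L-BFGS-B over log σ_individual,
   log σ_household (and log φ), with moment-based starting values
   (splitting the apparent latent heterogeneity unevenly across factors
   to break symmetry).  The log-σ floor (exp(−8)) is a flat corner of
   the surface; if a run collapses every component there after starting
   above it, jittered restarts are attempted.
4. **Joint refinement** — the profiled objective in step 3 neglects the
   β-dependence of the log-determinant and leaves a small bias in the
   fixed effects (the fast-vs-exact distinction familiar from
   penalized-least-squares mixed-model software).  A second L-BFGS-B
   pass over (β, log σ, log φ) maximizes the exact Laplace objective,
   with the inner Newton running over the random effects only.  The
   odds-ratio matrices skip this refinement: it shifts intercept-scale
   quantities but leaves within-model contrasts (log odds ratios)
   essentially unchanged, and a matrix fits ~p² models.

A dense tensor-product Gauss-Hermite evaluator (`quadrature_loglik`),
sharing no code with the Laplace path, serves as the correctness oracle
for problems with at most six random-effect levels; agreement is within
0.1 log-likelihood units on the test fixtures, and the σ = 0 case reduces
exactly (1e−8) to the fixed-effect GLM likelihood.

Wald covariance for β comes from the fixed-effect block of the inverse
joint Hessian at the optimum; SEs for the variance parameters from the
numeric curvature of the profiled objective on the log scale.  Profile
likelihood intervals (bisection on the signed likelihood-ratio statistic
against the χ²₁ quantile, re-optimizing all other parameters at each
candidate value) are available per parameter; they are the reporting
standard for the models this package emulates but are expensive across a
full odds-ratio matrix, so Wald is the matrix-scale default.  A σ
estimated at the floor is reported as converged-at-boundary with a
[0, σ̂] interval; a dispersion φ beyond e⁹ is flagged as the binomial
limit (with at most tens of trials the profile in log φ is flat there).
Any |coefficient| > 15 on the link scale raises a separation flag and the
affected odds-ratio cells are reported absent-with-diagnostic rather than
with meaningless intervals.

AIC = −2ℓ + 2p and BIC = −2ℓ + p·log n count fixed effects, variance
components and dispersion in p.  Model comparisons are reported as
oriented differences, Δ(focal, comparison) = IC(focal) − IC(comparison),
so a positive value favours the comparison model.

**Variance decomposition** is on the latent scale: marginal R² =
var_fixed/(var_fixed + var_random + var_resid), conditional R² adds
var_random to the numerator, adjusted ICC = var_random/(var_random +
var_resid).  The family-specific residual variance uses the log-normal
approximation ln(1/λ̄ + 1) for the Poisson log link (λ̄ the marginal
expected count) and π²/3 for logit links; the beta-binomial reuses the
logit value, so its decomposition is comparable only qualitatively across
families.  In an intercept-only model the marginal R² is exactly zero and
the adjusted ICC equals the conditional R².

## Co-occurrence analysis

One binomial-logit mixed model per outcome event, all other admissible
events as predictors, crossed random intercepts.  For an outcome inside a
mutual-exclusivity group, co-members are removed as contemporaneous
predictors (they are structurally zero whenever the outcome occurs) and
the group's "other/unspecified" label is dropped as the reference
category in every contemporaneous model.  Lag-1 models regress next
year's outcome on all of this year's events including the outcome's own
type; previous-year group co-members are *not* collinear and are kept
(only the reference label is dropped), which is what makes within-group
persistence cells estimable.  The household id attached to a lagged pair
is the outcome-year household, since membership can change between years.

Unadjusted sensitivity models fit one predictor at a time with identical
random-effects structure on identical rows.  The percentage difference is
100·(OR_unadjusted − OR_adjusted)/OR_adjusted; sign reversals are cells
significant in the adjusted fit whose unadjusted OR lies on the other
side of 1.  No multiple-testing correction is applied — significance
means the 95% interval excludes 1 — so with ~p² cells a 5% false-positive
rate among true nulls is expected and is exactly what the calibration
study verifies.

## Accumulation analysis

The three fits run on the same windowed counts: intercept-only Poisson
GLM ("bad luck"; the MLE is the sample mean rate), crossed-frailty
Poisson GLMM, and the beta-binomial GLMM as the estimable surrogate for
the literal urn (the literal urn, with draw-by-draw reinforcement and
state persisting across years, lives only in the generator).  The trial
count k always comes from the catalog, never from data maxima; counts
above k are a hard error.  Forward simulation of a fitted model redraws
random intercepts from the fitted σ — simulating a new population, not
conditioning on estimated entity modes — and returns per-year
cumulative-count histograms for envelope plots.

The autocorrelation model standardizes age on the analysis subset (mean
0, SD 1), squares the standardized age (square-after-standardize), and
leaves the lagged count unscaled; the scaling parameters are stored in
the fit's metadata.

## Heavy-tail characterization

Zeros are excluded (the tail models have positive support), then each
candidate distribution is ML-fitted to the tail above every observed
threshold and x_min is the KS-distance minimizer, ties broken toward the
smallest threshold.  The dialect for integer data follows the convention
of the standard reference implementation in this area: *discrete* power
law (Hurwitz-zeta normalization) and truncated Poisson, *continuous*
exponential and log-normal densities truncated at x_min; the choice is
recorded in output metadata since fit comparisons can be sensitive to it.
Vuong's statistic is √n·mean(d)/sd(d) over the pointwise log-likelihood
differences d on a common tail, with the common x_min defined as the
median of the two per-model estimates — with two values, their mean,
rounded down to the nearest observed value.  Identical models give
statistic 0 and p = 1 by convention (zero-variance case).  KS is a
selection objective only; no goodness-of-fit p-values are attached to it.

## Synthetic generators: what they emulate and what they do not

All generators expand one global seed into per-entity substreams
(`SeedSequence(seed, spawn_key=(stream, entity))`), so runs are
bit-reproducible and panels of different sizes share the draws of common
entities.

* **Poisson**: i.i.d. yearly counts — the null the accumulation analysis
  must reject when structure is present.
* **Frailty**: log-rate = log λ + u_i + v_h with log-normal entity
  effects; marginal moments follow the log-normal mixture closed forms
  used in the tests.
* **Urn**: a literal per-person Polya urn, k draws per year, reinforcement
  after every single draw (the natural reading of per-draw replacement),
  urn state persisting across years.  Exchangeability gives the exact
  beta-binomial law for cumulative totals that the chi-square test
  verifies.  Optional heterogeneity perturbs initial compositions
  per entity (shared within household when a household map is given),
  since the urn narrative is per-person but fitted models carry household
  effects.
* **Typed**: yearly binary vectors with target base logits, within-year
  cross-event log-odds ratios via sequential conditional sampling in
  catalog order (transparent, adequate for approximate target ORs; an
  exclusivity group is sampled as one categorical slot, so members never
  co-occur), lag-1 log-OR dependence on the previous year's vector, and
  per-event entity intercepts.
* **Autocorrelated counts**: the lag-1 Poisson model itself, with two
  deliberate guards.  The first year is an exogenous initial condition
  drawn without the entity effects — otherwise conditioning on it tilts
  the random-effect distribution (the dynamic-panel initial-conditions
  problem) and *no* estimator of the fitted model could recover the
  generating coefficient.  And yearly counts are capped at the
  instrument's maximum (13 by default), mirroring the hard ceiling a
  fixed event checklist imposes; without it the multiplicative feedback
  has a small probability of runaway trajectories whose extreme counts
  dominate the regression.

None of the generators emulate real-survey attrition mechanisms,
interview-mode effects, demographic composition beyond a uniform adult
age draw, or event-type-specific lag structure between *different*
events' counts.  Passing tests therefore demonstrate that the estimation
machinery recovers known structure of these forms at realistic rates and
panel sizes — not that real panel data satisfy the models' assumptions.

## Validation studies and problem sizes

The studies in `alepanel.studies` (re-run by `scripts/acceptance.py` and
asserted by the test suite) use these designs, chosen once as a balance
of statistical resolution and desk-scale runtime:

* Laplace oracle: 3 individuals × 2 households × 3 years, 31-node
  tensor quadrature.
* Exchangeability: 50,000 urns, 20 years × 6 draws.
* Frailty recovery: 100 replicates of 800 individuals × 20 years in
  200 four-person households, truths (λ = 0.86, σ_i = 0.34, σ_h = 0.36)
  from the published Swiss-row estimates.  Four-person households give
  each household-level effect ~80 observations, which keeps the
  log-scale Wald intervals for both variance components near nominal
  coverage at this scale.
* Lag recovery: one panel of 10,000 individuals × 11 years (100,000
  lag pairs), truths (rate 0.48, natural-scale lag 1.17, age 1.11,
  age² 1.02, σ = 0.40/0.39) from the published autocorrelation row.
* Selection: 100 urn replicates of 400 individuals × 20 years at the
  published Swiss urn composition (b = 25.57, w = 150.47, c = 1, k = 6),
  plus Poisson panels for the penalty-gap check.
* OR calibration: independence panels of 2,500 individuals × 20 years
  (50,000 person-years) over the 13-event catalog, several replicates
  (~600 null cells); planted OR = 2 recovery on one further panel.
* Tails: n = 10,000 samples; 10–20 seeds for the Vuong win rate.

## Known limitations

* Laplace ML shares the small-count bias of all Laplace-based mixed-model
  estimation; variance-component estimates for clusters with few
  observations are mildly attenuated, and Wald coverage for σ sits a few
  points under nominal in unfavourable designs (many two-person
  households, small σ).
* The beta-binomial's σ and φ split between-person and within-person
  overdispersion; on urn-generated data (where heterogeneity is
  persistent) φ can run to the binomial limit while σ absorbs the
  spread — both parameterizations fit the totals, and model *selection*
  is unaffected.
* Profile CIs assume a monotone profile within the search bracket; the
  search widens brackets but gives up (with an error) on pathological
  profiles.
* The typed generator's sequential conditional construction reproduces
  target odds ratios approximately, not exactly; recovery tolerances in
  the tests reflect that.
* Random slopes, GEE/Bayesian estimation, sampling weights, and
  simulation-based residual diagnostics are out of scope.
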