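# alepanel

Analysis of non-random patterns in **adverse life events** (ALEs) —
illness, bereavement, job loss, accidents — as recorded yearly in long
household panel surveys.  The package asks three questions about
person-year event data: which events co-occur within a year and predict
each other across years; whether yearly event *counts* are autocorrelated;
and which generative process best explains how events accumulate over
twenty years.  It is aimed at researchers in epidemiology, stress and life
course studies who work with panel event checklists, and at anyone who
needs a self-contained crossed-random-effects GLMM engine in Python.

Because the real microdata (large national household panels) are
access-restricted, the package ships synthetic generators that emulate
their statistical structure, so every analysis stage is testable end to
end.

## Models

**Co-occurrence.** For each outcome event *E_o*, a binomial-logit mixed
model over person-years

&nbsp;&nbsp;&nbsp;&nbsp;*E_o* ~ *E_1* + … + *E_p* + (1 | individual) + (1 | household)

gives adjusted odds ratios per predictor event; lag-1 variants regress
next year's outcome on this year's events.  Mutually exclusive event
subcategories (survey instruments that record at most one illness/accident
per year) are removed as contemporaneous predictors, with the "other"
category as the dropped reference.

**Autocorrelation.** A Poisson log-link mixed model for yearly counts:

&nbsp;&nbsp;&nbsp;&nbsp;events ~ 1 + age + age² + lag-1 events + (1 | individual) + (1 | household)

with age standardized and the lagged count unscaled; exp(b_lag) is the
multiplicative rate increase per additional prior-year event.

**Accumulation.** Three processes for the yearly count *Y_it*:

1. *bad luck*: *Y_it* ~ Poisson(λ), one homogeneous rate;
2. *frailty*: log λ_ih = log λ + *u_i* + *v_h*, crossed log-normal random
   intercepts, counts conditionally Poisson;
3. *Polya urn*: each person draws k balls a year from an urn with *w*
   white and *b* blue balls, every drawn colour reinforced with *c* extra
   balls.  Exchangeability makes cumulative draw totals
   BetaBinomial(m, α = b/c, β = w/c); the estimable surrogate is a
   beta-binomial mixed model in the Morris parameterization
   (μ = α/(α+β), φ = α+β, variance μ(1−μ)·n(φ+n)/(φ+1)).

Models are compared by ΔAIC/ΔBIC.  Estimation is maximum likelihood with
a Laplace-approximated marginal likelihood over the crossed random
effects (sparse damped Newton for the joint mode, log-determinant
correction, quasi-Newton outer optimization; a dense Gauss-Hermite
oracle verifies the approximation on small fixtures).

**Heavy tails.** Cumulative 20-year counts (zeros excluded) are fitted
above a KS-minimizing threshold x_min by a discrete power law, truncated
Poisson, and truncated continuous exponential and log-normal, compared
pairwise with Vuong's non-nested likelihood-ratio test at a common x_min.

## Worked example

Simulate a 500-person, 20-year panel from a self-reinforcing urn
(composition w = 150.47, b = 25.57, c = 1, k = 6 draws/year) and run the
accumulation comparison:

```python
import numpy as np
from alepanel import (UrnSpec, couple_households, simulate_urn_panel,
                      swiss_catalog, compare_accumulation)

catalog = swiss_catalog()
urn = UrnSpec(white=150.47, blue=25.57, reinforcement=1.0, draws_per_year=6)
panel = simulate_urn_panel(urn, 500, 20, seed=11,
                           household_map=couple_households(500, 2))
comp = compare_accumulation(panel, catalog, seed=0)
print(comp.summary().round(2))
print("AIC winner:", comp.aic_winner)
print("Delta AIC (Poisson - Frailty):", round(comp.delta_aic("poisson", "frailty"), 2))
print("Delta AIC (Frailty - Polya):  ", round(comp.delta_aic("frailty", "polya"), 2))
polya = comp.fits["polya"]
mu = 1 / (1 + np.exp(-polya.coefficients["(Intercept)"]))
print(f"Polya per-trial event probability p = {mu:.3f} (urn truth {urn.initial_risk:.3f})")
```

prints

```
           loglik  n_params       aic       bic
model
poisson -12030.08         1  24062.16  24069.38
frailty -12005.07         3  24016.13  24037.76
polya   -11935.38         4  23878.77  23907.61

AIC winner: polya
Delta AIC (Poisson - Frailty): 46.03
Delta AIC (Frailty - Polya):   137.36
Polya per-trial event probability p = 0.144 (urn truth 0.145)
```

Both heterogeneous-risk models beat the homogeneous Poisson, and the
self-reinforcing (beta-binomial) model — the generating process — wins
decisively, recovering the urn's per-trial event probability.

A configuration-driven run of the whole pipeline (simulate → filter →
analyses, with a manifest of output hashes) is available as
`ale run --config config.yaml`; see `ale --help` for the
simulate/cooccur/accumulate/tailfit subcommands.

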