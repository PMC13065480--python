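"""Simulation studies validating the estimation machinery.

Each function runs a self-contained study — analytic identity checks,
oracle comparisons, parameter-recovery and calibration experiments — and
returns a dict of plain numbers.  The studies double as the package's
reproducibility surface: ``scripts/acceptance.py`` re-runs them from a
single seed, and the test suite asserts their scientific properties.

Problem sizes default to a few hundred to a few thousand entities: large
enough for the asymptotic behaviour under test, small enough that the
whole battery runs on a laptop in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .accumulate import (
    BetaBinomialParams,
    compare_accumulation,
    fit_autocorrelation,
    fit_bad_luck,
    fit_frailty,
)
from .catalog import australian_catalog, swiss_catalog
from .cooccur import fit_contemporaneous
from .glmm import ModelSpec, fit_glmm, laplace_loglik, quadrature_loglik
from .panel import PanelDataset
from .synth import (
    AssociationSpec,
    FrailtyParams,
    UrnSpec,
    couple_households,
    simulate_autocorrelated_panel,
    simulate_frailty_panel,
    simulate_poisson_panel,
    simulate_typed_panel,
    simulate_urn_panel,
)
from .tailfit import estimate_xmin, fit_tail, vuong_compare

# Published beta-binomial shape estimates for the 20-year accumulation
# window of the two emulated national panels (alpha, beta), and the
# catalog trial counts they imply.
PUBLISHED_URN_SHAPES = {
    "swiss": (25.57, 150.47),
    "australian": (37.13, 884.75),
}

# Published frailty-row estimates (rate, sd_individual, sd_household)
# reused as simulation truths in the recovery studies.
PUBLISHED_FRAILTY = {
    "swiss": FrailtyParams(rate=0.86, sd_individual=0.34, sd_household=0.36),
    "australian": FrailtyParams(rate=0.52, sd_individual=0.47, sd_household=0.37),
}

# Published lag-1 autocorrelation coefficient (natural scale).
PUBLISHED_LAG_COEF = 1.17


def urn_identity_study() -> dict:
    """Analytic urn-to-beta-binomial identities for the published shapes."""
    a_alpha, a_beta = PUBLISHED_URN_SHAPES["australian"]
    s_alpha, s_beta = PUBLISHED_URN_SHAPES["swiss"]
    australian = BetaBinomialParams(alpha=a_alpha, beta=a_beta, trials=13)
    swiss = BetaBinomialParams(alpha=s_alpha, beta=s_beta, trials=6)
    return {
        "australian_mu": round(australian.mu, 2),
        "australian_phi": round(australian.phi, 2),
        "swiss_mu": round(swiss.mu, 2),
        "swiss_k_trials": swiss_catalog().k_trials,
        "australian_k_trials": australian_catalog().k_trials,
    }


def laplace_oracle_study(seed: int) -> dict:
    """Laplace vs dense Gauss-Hermite quadrature on a tiny crossed fixture,
    plus exact GLM agreement at sigma = 0."""
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "individual": np.repeat([0, 1, 2], 3),
            "household": [0, 0, 0, 0, 1, 1, 1, 1, 1],
            "y": rng.poisson(1.2, 9),
        }
    )
    spec = ModelSpec(family="poisson")
    diffs = []
    for beta, si, sh in [(0.2, 0.4, 0.3), (-0.3, 0.8, 0.2), (0.0, 0.15, 0.6)]:
        sig = {"individual": si, "household": sh}
        lap = laplace_loglik(spec, data, [beta], sig)
        quad = quadrature_loglik(spec, data, [beta], sig, nodes=31)
        diffs.append(abs(lap - quad))
    glm_diff = abs(
        laplace_loglik(spec, data, [0.25], {"individual": 0.0, "household": 0.0})
        - stats.poisson.logpmf(data["y"], np.exp(0.25)).sum()
    )
    return {
        "max_abs_diff_vs_quadrature": float(max(diffs)),
        "abs_diff_vs_glm_at_sigma0": float(glm_diff),
        "n": len(data),
    }


def urn_exchangeability_study(seed: int, n_individuals: int = 50000) -> dict:
    """Chi-square GOF of literal-urn 20-year totals against the
    beta-binomial law implied by exchangeability."""
    spec = UrnSpec(white=6.0, blue=2.0, reinforcement=2.0, draws_per_year=6)
    panel = simulate_urn_panel(spec, n_individuals, 20, seed=seed)
    cum = panel.data.groupby("id")["count"].sum().to_numpy()
    m = 20 * spec.draws_per_year
    alpha = spec.blue / spec.reinforcement
    beta = spec.white / spec.reinforcement
    pmf = stats.betabinom.pmf(np.arange(m + 1), m, alpha, beta)
    obs = np.bincount(cum, minlength=m + 1)
    exp = pmf * n_individuals
    keep = exp >= 5
    obs2, exp2 = obs[keep], exp[keep]
    if (~keep).any():
        obs2 = np.append(obs2, obs[~keep].sum())
        exp2 = np.append(exp2, exp[~keep].sum())
    chi2 = float(((obs2 - exp2) ** 2 / exp2).sum())
    p = float(stats.chi2.sf(chi2, len(obs2) - 1))
    return {"gof_p_value": p, "n": n_individuals}


def frailty_recovery_study(
    seed: int, reps: int = 100, n_individuals: int = 800, n_years: int = 20
) -> dict:
    """Wald-CI coverage of the generating frailty parameters over replicate
    panels simulated at the published Swiss-row truths.

    Four-person households give each household-level effect ~80
    observations, keeping the log-scale Wald intervals for both variance
    components near nominal coverage at this scale.
    """
    truth = PUBLISHED_FRAILTY["swiss"]
    hh = couple_households(n_individuals, 4)
    cover = {"rate": 0, "sd_individual": 0, "sd_household": 0}
    for r in range(reps):
        panel = simulate_frailty_panel(truth, hh, n_years, seed=seed * 100000 + r)
        fit = fit_frailty(panel, seed=r)
        lo, hi = fit.wald_ci["(Intercept)"]
        cover["rate"] += np.exp(lo) <= truth.rate <= np.exp(hi)
        ci = fit.sigma_ci
        cover["sd_individual"] += ci["individual"][0] <= truth.sd_individual <= ci["individual"][1]
        cover["sd_household"] += ci["household"][0] <= truth.sd_household <= ci["household"][1]
    return {
        "coverage_rate": cover["rate"] / reps,
        "coverage_sd_individual": cover["sd_individual"] / reps,
        "coverage_sd_household": cover["sd_household"] / reps,
        "min_coverage": min(cover.values()) / reps,
        "n": reps,
    }


def lag_recovery_study(
    seed: int, n_individuals: int = 10000, n_years: int = 11
) -> dict:
    """Recovery of the published lag-1 natural-scale coefficient from a
    panel generated at the published autocorrelation-model truths."""
    panel = simulate_autocorrelated_panel(
        rate=0.48,
        lag_coef=np.log(PUBLISHED_LAG_COEF),
        n_individuals=n_individuals,
        n_years=n_years,
        seed=seed,
        age_coef=np.log(1.11),
        age2_coef=np.log(1.02),
        sd_individual=0.40,
        sd_household=0.39,
    )
    fit = fit_autocorrelation(panel, seed=seed)
    est = fit.coefficients["lag_count"]
    return {
        "lag_coefficient_natural": float(np.exp(est)),
        "abs_error_log_scale": float(abs(est - np.log(PUBLISHED_LAG_COEF))),
        "n": fit.n_obs,
    }


def selection_study(
    seed: int, reps: int = 100, n_individuals: int = 400, n_years: int = 20
) -> dict:
    """AIC model selection: Polya-preferred rate on urn-generated panels
    (published Swiss urn composition) and the bad-luck-vs-frailty AIC gap
    on Poisson-generated panels.

    Uses the fast profiled-Laplace fits (``refine=False``): the AIC gaps
    under judgment are tens to hundreds of units, the profiled-vs-exact
    log-likelihood difference a fraction of one.
    """
    s_alpha, s_beta = PUBLISHED_URN_SHAPES["swiss"]
    urn = UrnSpec(white=s_beta, blue=s_alpha, reinforcement=1.0, draws_per_year=6)
    catalog = swiss_catalog()
    hh = couple_households(n_individuals, 2)
    wins = 0
    for r in range(reps):
        panel = simulate_urn_panel(
            urn, n_individuals, n_years, seed=seed * 100000 + r, household_map=hh
        )
        comp = compare_accumulation(panel, catalog, seed=r, refine=False)
        wins += comp.aic_winner == "polya"
    gaps = []
    for r in range(max(10, reps // 5)):
        panel = simulate_poisson_panel(0.62, n_individuals, n_years, seed=seed * 100000 + 50000 + r)
        gaps.append(fit_bad_luck(panel).aic - fit_frailty(panel, seed=r, refine=False).aic)
    within_penalty = float(np.mean([g <= 4.0 for g in gaps]))
    return {
        "polya_selected_rate": wins / reps,
        "poisson_within_penalty_rate": within_penalty,
        "median_poisson_frailty_gap": float(np.median(gaps)),
        "n": reps,
    }


def or_calibration_study(
    seed: int, reps: int = 3, n_individuals: int = 2500, n_years: int = 20
) -> dict:
    """Per-cell false-positive rate of contemporaneous OR matrices on
    independence panels, and recovery of a single planted OR = 2 pair."""
    catalog = australian_catalog()
    sig = []
    for r in range(reps):
        assoc = AssociationSpec.from_rates(
            catalog, sd_individual=0.3, sd_household=0.3
        )
        panel = simulate_typed_panel(
            assoc, catalog, n_individuals, n_years, seed=seed * 1000 + r
        )
        mat = fit_contemporaneous(panel, catalog, seed=r)
        sig += [cell.significant for cell in mat.estimates.values()]
    p = catalog.n_events
    planted = np.zeros((p, p))
    a, b = catalog.events[0], catalog.events[1]
    planted[0, 1] = planted[1, 0] = np.log(2.0)
    assoc = AssociationSpec.from_rates(
        catalog, contemporaneous=planted, sd_individual=0.3, sd_household=0.3
    )
    panel = simulate_typed_panel(assoc, catalog, n_individuals, n_years, seed=seed * 1000 + 999)
    mat = fit_contemporaneous(panel, catalog, seed=reps)
    est = mat.get(a, b)
    return {
        "false_positive_rate": float(np.mean(sig)),
        "n_null_cells": len(sig),
        "planted_or_estimate": float(est.odds_ratio),
        "n": reps * n_individuals * n_years,
    }


def tail_study(seed: int, n_sample: int = 10000, vuong_seeds: int = 15) -> dict:
    """Power-law exponent recovery and Vuong-test behaviour."""
    rng = np.random.default_rng(seed)
    x_grid = np.arange(1, 200001)
    pmf = x_grid ** (-2.5)
    pmf /= pmf.sum()
    sample = rng.choice(x_grid, size=n_sample, p=pmf)
    pl = estimate_xmin(sample, "powerlaw")
    self_v = vuong_compare(pl, pl, sample)
    wins = 0
    for s in range(vuong_seeds):
        r = np.random.default_rng(seed * 1000 + s)
        y = np.round(np.exp(r.normal(1.0, 0.7, n_sample))).astype(int)
        y = y[y > 0]
        ln_fit = estimate_xmin(y, "lognormal")
        pl_fit = estimate_xmin(y, "powerlaw")
        v = vuong_compare(ln_fit, pl_fit, y)
        wins += (v.statistic > 0) and (v.p_value < 0.05)
    return {
        "powerlaw_exponent": float(pl.params["alpha"]),
        "vuong_self_statistic": float(self_v.statistic),
        "vuong_lognormal_win_rate": wins / vuong_seeds,
        "n": n_sample,
    }
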