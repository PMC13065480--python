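"""Accumulation of yearly event counts: three generative processes compared.

The yearly event count Y_it of individual i is modelled three ways:

* "bad luck": Y_it ~ Poisson(lambda), one homogeneous rate — a fixed
  intercept and nothing else.
* frailty: Y_it ~ Poisson(lambda_ih), log lambda_ih = log lambda + u_i +
  v_h with crossed log-normal random intercepts — heterogeneous but
  time-constant risk.
* Polya urn: Y_it ~ BetaBinomial(k, mu_ih, phi) on the k possible event
  slots per year, logit link on mu, crossed random intercepts — the
  estimable surrogate for a self-reinforcing urn whose cumulative draw
  totals are beta-binomial with shapes alpha = b/c, beta = w/c.

Models are compared by AIC/BIC differences oriented so a positive
difference favours the model subtracted *from* (the right-hand model of
each ordered pair fits better when the difference is positive).

Also here: the lag-1 autocorrelation model for counts
(events ~ age + age^2 + lag-1 events + crossed intercepts) and forward
simulation of a fitted model for envelope plots of cumulative counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import EventCatalog
from .glmm import FitResult, ModelSpec, fit_glmm
from .panel import PanelDataset, lag_align
from .synth import UrnSpec

__all__ = [
    "BetaBinomialParams",
    "FitComparison",
    "urn_to_betabinom",
    "betabinom_variance",
    "fit_bad_luck",
    "fit_frailty",
    "fit_polya",
    "compare_accumulation",
    "simulate_fitted",
    "fit_autocorrelation",
]


@dataclass(frozen=True)
class BetaBinomialParams:
    """Beta-binomial in both shape (alpha, beta) and Morris (mu, phi) forms.

    mu = alpha / (alpha + beta) is the per-trial event probability,
    phi = alpha + beta the dispersion, and ``trials`` the number n of
    event slots; the count variance is mu(1-mu) * n(phi+n)/(phi+1).
    """

    alpha: float
    beta: float
    trials: int

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("shape parameters must be positive")
        if self.trials < 1:
            raise ValueError("trials must be at least 1")

    @property
    def mu(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def phi(self) -> float:
        return self.alpha + self.beta

    @classmethod
    def from_morris(cls, mu: float, phi: float, trials: int) -> "BetaBinomialParams":
        return cls(alpha=mu * phi, beta=(1.0 - mu) * phi, trials=trials)


def urn_to_betabinom(spec: UrnSpec) -> BetaBinomialParams:
    """Map an urn (w, b, c, k draws/year) to the beta-binomial it induces:
    shapes alpha = b/c and beta = w/c.  Requires reinforcement c > 0 (at
    c = 0 the process is plain binomial, not beta-binomial)."""
    if spec.reinforcement == 0:
        raise ValueError("no reinforcement (c = 0) induces a binomial, not a beta-binomial")
    return BetaBinomialParams(
        alpha=spec.blue / spec.reinforcement,
        beta=spec.white / spec.reinforcement,
        trials=spec.draws_per_year,
    )


def betabinom_variance(params: BetaBinomialParams) -> float:
    """Morris variance V = mu (1 - mu) * n (phi + n) / (phi + 1)."""
    n, mu, phi = params.trials, params.mu, params.phi
    return mu * (1.0 - mu) * n * (phi + n) / (phi + 1.0)


# ---------------------------------------------------------------------------
# the three accumulation fits
# ---------------------------------------------------------------------------


def _count_frame(panel: PanelDataset) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "individual": panel.data["id"].to_numpy(),
            "household": panel.data["hh_id"].to_numpy(),
            "y": panel.yearly_counts().to_numpy(),
        }
    )
    return df


def fit_bad_luck(panel: PanelDataset) -> FitResult:
    """Intercept-only Poisson GLM: the rate estimate is the sample mean."""
    data = _count_frame(panel)
    fit = fit_glmm(ModelSpec(family="poisson", grouping=()), data)
    if data["y"].sum() == 0:
        fit.boundary.append("rate")
        fit.warnings.append("all counts zero: rate at boundary")
    return fit


def fit_frailty(panel: PanelDataset, seed: int = 0, refine: bool = True) -> FitResult:
    """Poisson mixed model with crossed individual/household intercepts."""
    return fit_glmm(ModelSpec(family="poisson"), _count_frame(panel), seed=seed,
                    refine_beta=refine)


def fit_polya(
    panel: PanelDataset, catalog: EventCatalog, seed: int = 0, refine: bool = True
) -> FitResult:
    """Beta-binomial (Morris mu, phi) mixed model on (events, k - events).

    The trial count k comes from the catalog, never from data maxima;
    counts exceeding k are a hard error naming the offending rows.
    """
    data = _count_frame(panel)
    k = catalog.k_trials
    over = np.flatnonzero((data["y"] > k).to_numpy())
    if len(over):
        rows = panel.data.iloc[over][["id", "year"]].values.tolist()
        raise ValueError(f"counts exceed k_trials={k} at rows {rows[:10]}")
    return fit_glmm(ModelSpec(family="betabinom", trials=k), data, seed=seed,
                    refine_beta=refine)


@dataclass
class FitComparison:
    """The three accumulation fits plus oriented AIC/BIC differences.

    ``delta_aic(a, b)`` = AIC(a) - AIC(b); positive means b fits better.
    """

    fits: dict[str, FitResult]

    def delta_aic(self, focal: str, comparison: str) -> float:
        return self.fits[focal].aic - self.fits[comparison].aic

    def delta_bic(self, focal: str, comparison: str) -> float:
        return self.fits[focal].bic - self.fits[comparison].bic

    @property
    def aic_winner(self) -> str:
        return min(self.fits, key=lambda m: self.fits[m].aic)

    @property
    def bic_winner(self) -> str:
        return min(self.fits, key=lambda m: self.fits[m].bic)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            rows.append(
                {
                    "model": name,
                    "loglik": fit.loglik,
                    "n_params": fit.n_params,
                    "aic": fit.aic,
                    "bic": fit.bic,
                }
            )
        df = pd.DataFrame(rows).set_index("model")
        return df


def compare_accumulation(
    panel: PanelDataset, catalog: EventCatalog, seed: int = 0, refine: bool = True
) -> FitComparison:
    """Fit bad-luck, frailty and Polya models to the same counts and compare.

    The headline differences follow the convention of subtracting the
    richer model: (poisson - frailty) and (frailty - polya), so positive
    values favour the model on the right of each pair.  ``refine=False``
    compares the fast profiled-Laplace fits instead — the log-likelihood
    difference between the two is a fraction of a unit, far below the
    AIC gaps being judged, at a fraction of the cost.
    """
    fits = {
        "poisson": fit_bad_luck(panel),
        "frailty": fit_frailty(panel, seed=seed, refine=refine),
        "polya": fit_polya(panel, catalog, seed=seed, refine=refine),
    }
    return FitComparison(fits=fits)


# ---------------------------------------------------------------------------
# forward simulation of a fitted accumulation model
# ---------------------------------------------------------------------------


def simulate_fitted(
    fit: FitResult,
    catalog: EventCatalog | None,
    n_individuals: int,
    n_years: int,
    reps: int = 1000,
    seed: int = 0,
    household_size: int = 2,
) -> np.ndarray:
    """Forward-simulate a fitted accumulation model.

    Draws ``reps`` fresh panels from the fitted parameters — new random
    intercepts for every entity, never the estimated modes — and returns
    per-year histograms of cumulative counts: an integer array of shape
    (reps, n_years, max_count + 1) for envelope plots against the
    empirical distribution.
    """
    rng = np.random.default_rng(seed)
    b0 = fit.coefficients["(Intercept)"]
    sd_i = fit.sigma.get("individual", 0.0)
    sd_h = fit.sigma.get("household", 0.0)
    hh = np.arange(n_individuals) // household_size
    n_hh = hh.max() + 1
    cumulative = np.empty((reps, n_individuals, n_years), dtype=np.int64)
    for r in range(reps):
        u = rng.normal(0.0, sd_i, size=n_individuals)
        v = rng.normal(0.0, sd_h, size=n_hh)[hh]
        eta = b0 + u + v
        if fit.spec.family == "poisson":
            lam = np.exp(eta)
            counts = rng.poisson(lam[:, None], size=(n_individuals, n_years))
        elif fit.spec.family == "betabinom":
            k = fit.spec.trials
            mu = 1.0 / (1.0 + np.exp(-eta))
            a, b = mu * fit.phi, (1.0 - mu) * fit.phi
            p = rng.beta(a[:, None], b[:, None], size=(n_individuals, n_years))
            counts = rng.binomial(k, p)
        else:
            raise ValueError(f"cannot forward-simulate family {fit.spec.family}")
        cumulative[r] = np.cumsum(counts, axis=1)
    max_count = int(cumulative.max())
    hist = np.zeros((reps, n_years, max_count + 1), dtype=np.int64)
    for r in range(reps):
        for t in range(n_years):
            hist[r, t] = np.bincount(cumulative[r, :, t], minlength=max_count + 1)
    return hist


# ---------------------------------------------------------------------------
# lag-1 autocorrelation of counts
# ---------------------------------------------------------------------------


def fit_autocorrelation(panel: PanelDataset, seed: int = 0) -> FitResult:
    """Poisson mixed model of next year's count on this year's count and age.

    Age (outcome year) is standardized to mean 0, SD 1 on the analysis
    subset; the squared term is the square of the standardized age; the
    lagged count enters unscaled.  The scaling parameters are stored in
    ``fit.meta`` so natural-scale Table-style estimates stay reproducible.
    """
    pairs = lag_align(panel)
    if pairs.empty:
        raise ValueError("no adjacent-year pairs for autocorrelation analysis")
    if "pred_count" not in pairs.columns:
        counts = panel.data.assign(count=panel.yearly_counts())
        pairs = lag_align(
            PanelDataset(
                data=counts[["id", "hh_id", "year", "age", "count"]],
                catalog=None,
                provenance=panel.provenance,
            )
        )
    if pairs["age"].isna().any():
        raise ValueError("age required for the autocorrelation model")
    age_mean = float(pairs["age"].mean())
    age_sd = float(pairs["age"].std(ddof=0)) or 1.0
    data = pd.DataFrame(
        {
            "individual": pairs["id"],
            "household": pairs["hh_id"],
            "y": pairs["out_count"].astype(int),
            "lag_count": pairs["pred_count"].astype(float),
            "age_z": (pairs["age"] - age_mean) / age_sd,
        }
    )
    data["age_z2"] = data["age_z"] ** 2
    spec = ModelSpec(family="poisson", fixed_terms=("age_z", "age_z2", "lag_count"))
    fit = fit_glmm(spec, data, seed=seed)
    fit.meta["age_mean"] = age_mean
    fit.meta["age_sd"] = age_sd
    return fit
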