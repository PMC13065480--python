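"""Heavy-tail characterization of cumulative event counts.

Four candidate models are fitted by maximum likelihood to the tail of a
positive-integer sample above a threshold x_min, which is itself estimated
by minimizing the Kolmogorov-Smirnov distance between the fitted and
empirical tail CDFs over candidate thresholds (every observed value).
Candidates follow the conventional dialect for integer data: a *discrete*
power law normalized by the Hurwitz zeta function, a zero-truncated
Poisson, and *continuous* exponential and log-normal densities truncated
at x_min.  Non-nested fits are compared with Vuong's likelihood-ratio
test on a common x_min (the median — i.e. mean, rounded down to an
observed value — of the two per-model estimates).

KS here is purely a threshold-selection objective; no goodness-of-fit
p-values are attached to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "TailFit",
    "VuongResult",
    "exclude_zeros",
    "estimate_xmin",
    "fit_tail",
    "vuong_compare",
    "DISTRIBUTIONS",
]

DISTRIBUTIONS = ("poisson", "exponential", "lognormal", "powerlaw")


@dataclass(frozen=True)
class TailFit:
    distribution: str
    params: dict[str, float]
    xmin: int
    ks: float
    n_tail: int
    loglik: float


@dataclass(frozen=True)
class VuongResult:
    """Signed Vuong statistic (positive favours model A), two-sided p-value,
    and the common x_min both models were re-fitted at."""

    statistic: float
    p_value: float
    xmin: int
    loglik_a: float
    loglik_b: float
    n_tail: int
    warnings: tuple[str, ...] = ()


def exclude_zeros(counts: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop zero counts (tail models need positive support); returns the
    remaining counts and how many were removed."""
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    kept = counts[counts > 0].astype(int)
    if kept.size == 0:
        raise ValueError("all counts are zero; nothing to fit")
    return kept, int(counts.size - kept.size)


# ---------------------------------------------------------------------------
# per-distribution ML fits on the tail x >= xmin
# ---------------------------------------------------------------------------


def _fit_powerlaw(tail: np.ndarray, xmin: int) -> dict[str, float]:
    logsum = np.sum(np.log(tail))
    n = tail.size

    def nll(a):
        return a * logsum + n * np.log(special.zeta(a, xmin))

    res = optimize.minimize_scalar(nll, bounds=(1.0001, 20.0), method="bounded")
    return {"alpha": float(res.x)}


def _powerlaw_cdf(x: np.ndarray, params, xmin: int) -> np.ndarray:
    a = params["alpha"]
    z0 = special.zeta(a, xmin)
    return 1.0 - special.zeta(a, np.asarray(x) + 1.0) / z0


def _powerlaw_logpmf(x: np.ndarray, params, xmin: int) -> np.ndarray:
    a = params["alpha"]
    return -a * np.log(x) - np.log(special.zeta(a, xmin))


def _fit_exponential(tail: np.ndarray, xmin: int) -> dict[str, float]:
    excess = tail.mean() - xmin
    if excess <= 0:
        raise ValueError("degenerate tail: no spread above x_min")
    return {"rate": float(1.0 / excess)}


def _exponential_cdf(x, params, xmin):
    lam = params["rate"]
    return 1.0 - np.exp(-lam * (np.asarray(x, dtype=float) - xmin))


def _exponential_logpdf(x, params, xmin):
    lam = params["rate"]
    return np.log(lam) - lam * (np.asarray(x, dtype=float) - xmin)


def _fit_lognormal(tail: np.ndarray, xmin: int) -> dict[str, float]:
    logs = np.log(tail.astype(float))
    if logs.std() < 1e-12:
        raise ValueError("degenerate tail: a single repeated value")

    def nll(p):
        mu, log_s = p
        s = np.exp(log_s)
        surv = stats.norm.sf((np.log(xmin) - mu) / s)
        if surv <= 0:
            return np.inf
        ll = stats.norm.logpdf(logs, mu, s) - np.log(tail) - np.log(surv)
        return -ll.sum()

    res = optimize.minimize(
        nll, x0=[logs.mean(), np.log(max(logs.std(), 0.1))], method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10},
    )
    mu, log_s = res.x
    return {"mu": float(mu), "sigma": float(np.exp(log_s))}


def _lognormal_cdf(x, params, xmin):
    mu, s = params["mu"], params["sigma"]
    surv = stats.norm.sf((np.log(xmin) - mu) / s)
    if surv <= 0:
        return np.ones_like(np.asarray(x, dtype=float))
    c0 = 1.0 - surv
    c = stats.norm.cdf((np.log(np.asarray(x, dtype=float)) - mu) / s)
    return (c - c0) / surv


def _lognormal_logpdf(x, params, xmin):
    mu, s = params["mu"], params["sigma"]
    x = np.asarray(x, dtype=float)
    surv = stats.norm.sf((np.log(xmin) - mu) / s)
    return stats.norm.logpdf(np.log(x), mu, s) - np.log(x) - np.log(surv)


def _fit_poisson(tail: np.ndarray, xmin: int) -> dict[str, float]:
    if np.unique(tail).size < 2:
        raise ValueError("degenerate tail: a single repeated value")

    def nll(log_lam):
        lam = np.exp(log_lam)
        surv = stats.poisson.sf(xmin - 1, lam)
        if surv <= 0:
            return np.inf
        return -(stats.poisson.logpmf(tail, lam).sum() - tail.size * np.log(surv))

    res = optimize.minimize_scalar(nll, bounds=(-10, 12), method="bounded")
    return {"rate": float(np.exp(res.x))}


def _poisson_cdf(x, params, xmin):
    lam = params["rate"]
    base = stats.poisson.cdf(xmin - 1, lam)
    return (stats.poisson.cdf(np.asarray(x), lam) - base) / (1.0 - base)


def _poisson_logpmf(x, params, xmin):
    lam = params["rate"]
    return stats.poisson.logpmf(np.asarray(x), lam) - np.log(stats.poisson.sf(xmin - 1, lam))


_FITTERS = {
    "powerlaw": (_fit_powerlaw, _powerlaw_cdf, _powerlaw_logpmf),
    "exponential": (_fit_exponential, _exponential_cdf, _exponential_logpdf),
    "lognormal": (_fit_lognormal, _lognormal_cdf, _lognormal_logpdf),
    "poisson": (_fit_poisson, _poisson_cdf, _poisson_logpmf),
}


def _ks_statistic(tail: np.ndarray, distribution: str, params, xmin: int) -> float:
    """Max distance between fitted and empirical tail CDFs at observed values."""
    _, cdf, _ = _FITTERS[distribution]
    values = np.unique(tail)
    ecdf = np.searchsorted(np.sort(tail), values, side="right") / tail.size
    fitted = cdf(values, params, xmin)
    return float(np.max(np.abs(ecdf - fitted)))


def fit_tail(counts: np.ndarray, distribution: str, xmin: int) -> TailFit:
    """ML fit of one tail model above a given x_min (must be an observed value)."""
    if distribution not in _FITTERS:
        raise ValueError(f"unknown distribution {distribution!r}")
    counts = np.asarray(counts).astype(int)
    if xmin not in counts:
        raise ValueError("x_min must be an observed value")
    tail = counts[counts >= xmin]
    fitter, cdf, logf = _FITTERS[distribution]
    params = fitter(tail, xmin)
    ll = float(np.sum(logf(tail, params, xmin)))
    ks = _ks_statistic(tail, distribution, params, xmin)
    return TailFit(
        distribution=distribution,
        params=params,
        xmin=int(xmin),
        ks=ks,
        n_tail=int(tail.size),
        loglik=ll,
    )


def estimate_xmin(
    counts: np.ndarray, distribution: str, min_tail: int = 3
) -> TailFit:
    """Choose x_min by scanning observed values and minimizing the KS
    distance of the ML tail fit; ties break toward the smallest x_min."""
    counts = np.asarray(counts).astype(int)
    values = np.unique(counts)
    if values.size < 2:
        raise ValueError("need at least 2 distinct values to estimate x_min")
    if values.size < 10:
        warnings.warn("fewer than 10 distinct values: x_min estimate is unstable")
    best: TailFit | None = None
    for xmin in values:
        if np.sum(counts >= xmin) < max(min_tail, 2):
            break
        try:
            fit = fit_tail(counts, distribution, int(xmin))
        except ValueError:
            continue
        if best is None or fit.ks < best.ks - 1e-12:
            best = fit
    if best is None:
        raise ValueError("no admissible x_min candidate")
    return best


def vuong_compare(fit_a: TailFit, fit_b: TailFit, counts: np.ndarray) -> VuongResult:
    """Vuong's non-nested likelihood-ratio test between two tail fits.

    Both models are re-fitted at the common x_min = median of the two
    estimated thresholds (their mean, rounded down to an observed value).
    Positive statistics favour model A; the p-value is two-sided normal.
    """
    counts = np.asarray(counts).astype(int)
    target = 0.5 * (fit_a.xmin + fit_b.xmin)
    observed = np.unique(counts)
    candidates = observed[observed <= target]
    xmin = int(candidates.max()) if candidates.size else int(observed.min())
    ra = fit_tail(counts, fit_a.distribution, xmin)
    rb = fit_tail(counts, fit_b.distribution, xmin)
    tail = counts[counts >= xmin]
    n = tail.size
    warns: list[str] = []
    if n < 3:
        raise ValueError("common tail has fewer than 3 points")
    if n < 10:
        warns.append("common tail has fewer than 10 points")
    _, _, logf_a = _FITTERS[ra.distribution]
    _, _, logf_b = _FITTERS[rb.distribution]
    d = logf_a(tail, ra.params, xmin) - logf_b(tail, rb.params, xmin)
    sd = float(np.std(d, ddof=1)) if n > 1 else 0.0
    if sd < 1e-12:
        stat = 0.0
        p = 1.0
    else:
        stat = float(np.sqrt(n) * np.mean(d) / sd)
        p = float(2.0 * stats.norm.sf(abs(stat)))
    return VuongResult(
        statistic=stat,
        p_value=p,
        xmin=xmin,
        loglik_a=ra.loglik,
        loglik_b=rb.loglik,
        n_tail=n,
        warnings=tuple(warns),
    )
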