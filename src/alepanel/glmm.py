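"""Mixed-model estimation with crossed random intercepts via Laplace.

Implements maximum-likelihood estimation for Poisson (log link), binomial
(logit) and beta-binomial (logit, Morris mean/dispersion parameterization)
regression with crossed individual and household random intercepts:

    eta = X beta + u_{i(r)} + v_{h(r)},   u_i ~ N(0, sigma_i^2),
                                          v_h ~ N(0, sigma_h^2).

The marginal likelihood integrates the random effects out; the integral is
approximated by Laplace: the joint penalized log-likelihood is maximized
over (beta, u, v) by damped Newton with sparse linear algebra, and the
log-determinant of the negative Hessian over the stacked random-effect
vector supplies the Gaussian correction.  The outer optimization runs over
the variance (and dispersion) parameters on the log scale, with the fixed
effects profiled inside the Newton step, as in lme4's penalized
least-squares formulation.

The beta-binomial follows Morris: mean mu with logit link, dispersion phi
with log link, count variance V = mu (1 - mu) n (phi + n) / (phi + 1) for
n trials; the underlying Beta shapes are alpha = mu phi, beta = (1-mu) phi.

:func:`quadrature_loglik` provides a brute-force dense Gauss-Hermite
evaluation of the same marginal likelihood for problems with at most six
random-effect levels; it shares no code with the Laplace path and exists
for verification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.special import betaln, gammaln, logsumexp, polygamma, psi
from scipy.stats import chi2, norm

__all__ = [
    "ModelSpec",
    "FitResult",
    "VarianceDecomposition",
    "fit_glmm",
    "laplace_loglik",
    "profile_ci",
    "variance_decomposition",
    "quadrature_loglik",
]

_SIGMA_LOG_FLOOR = -8.0  # below this, a variance component is at the zero boundary
_SEPARATION_THRESHOLD = 15.0  # |beta| beyond this on the link scale flags separation
_RIDGE = 1e-8  # Levenberg-style guard for collinear fixed-effect columns


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: family, response, fixed terms, grouping factors, trials.

    family: "poisson" (log link), "binomial" or "betabinom" (logit link).
    fixed_terms: covariate column names; an intercept is always included.
    grouping: data columns holding the crossed grouping factors.
    trials: number of trials per row, required for (beta-)binomial.
    """

    family: str
    response: str = "y"
    fixed_terms: tuple[str, ...] = ()
    grouping: tuple[str, ...] = ("individual", "household")
    trials: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "binomial", "betabinom"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("binomial", "betabinom") and self.trials is None:
            raise ValueError(f"{self.family} requires trials")
        if self.family == "poisson" and self.trials is not None:
            raise ValueError("poisson takes no trials")

    @property
    def has_dispersion(self) -> bool:
        return self.family == "betabinom"


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: dict[str, float]
    se: dict[str, float]
    wald_ci: dict[str, tuple[float, float]]
    sigma: dict[str, float]
    sigma_ci: dict[str, tuple[float, float]]
    phi: float | None
    phi_ci: tuple[float, float] | None
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_params: int
    converged: bool
    boundary: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    eta_fixed: np.ndarray | None = None
    _problem: "object" = None
    _theta: np.ndarray | None = None

    def natural(self, name: str) -> tuple[float, float, float]:
        """Estimate and Wald CI on the natural (exp) scale for a coefficient."""
        lo, hi = self.wald_ci[name]
        return float(np.exp(self.coefficients[name])), float(np.exp(lo)), float(np.exp(hi))

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "coefficients": self.coefficients,
            "se": self.se,
            "wald_ci": {k: list(v) for k, v in self.wald_ci.items()},
            "sigma": self.sigma,
            "sigma_ci": {k: list(v) for k, v in self.sigma_ci.items()},
            "phi": self.phi,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "boundary": self.boundary,
            "warnings": self.warnings,
        }


@dataclass(frozen=True)
class VarianceDecomposition:
    marginal_r2: float
    conditional_r2: float
    adjusted_icc: float


# ---------------------------------------------------------------------------
# family derivatives on the linear predictor scale
# ---------------------------------------------------------------------------


def _family_const(family, y, trials):
    """Data-only part of the log-likelihood, cached across evaluations."""
    if family == "poisson":
        return -gammaln(y + 1.0)
    k = trials
    return gammaln(k + 1.0) - gammaln(y + 1.0) - gammaln(k - y + 1.0)


def _poisson_eval(eta, y, trials, phi, const=None):
    if const is None:
        const = _family_const("poisson", y, trials)
    mu = np.exp(np.clip(eta, -30, 30))
    ll = y * eta - mu + const
    return ll, y - mu, mu


def _binomial_eval(eta, y, trials, phi, const=None):
    if const is None:
        const = _family_const("binomial", y, trials)
    k = trials
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    ll = const + y * eta - k * np.log1p(np.exp(np.clip(eta, -30, 30)))
    w = np.maximum(k * mu * (1.0 - mu), 1e-10)
    return ll, y - k * mu, w


def _betabinom_eval(eta, y, trials, phi, const=None):
    if const is None:
        const = _family_const("betabinom", y, trials)
    n = trials
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = const + betaln(y + a, n - y + b) - betaln(a, b)
    A = psi(y + a) - psi(n - y + b) - psi(a) + psi(b)
    dmu = mu * (1.0 - mu)
    g = phi * dmu * A
    dA = phi * (polygamma(1, y + a) + polygamma(1, n - y + b) - polygamma(1, a) - polygamma(1, b))
    d2 = phi * ((1.0 - 2.0 * mu) * dmu * A + dmu * dmu * dA)
    w = np.maximum(-d2, 1e-10)  # clamp: observed information, kept positive
    return ll, g, w


_FAMILIES = {"poisson": _poisson_eval, "binomial": _binomial_eval, "betabinom": _betabinom_eval}


# ---------------------------------------------------------------------------
# problem container
# ---------------------------------------------------------------------------


class _Problem:
    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        self.n_total = len(data)
        if self.n_total == 0:
            raise ValueError("empty data")
        y_raw = data[spec.response].to_numpy(dtype=float)
        if np.any(y_raw < 0):
            raise ValueError("negative outcomes")
        if spec.trials is not None and np.any(y_raw > spec.trials):
            bad = np.flatnonzero(y_raw > spec.trials)[:5]
            raise ValueError(f"outcome exceeds trials={spec.trials} at rows {bad.tolist()}")
        # intercept-only models: collapse duplicate (groups, y) rows into
        # weighted rows — the likelihood is identical and much cheaper
        self.weights: np.ndarray | None = None
        if not spec.fixed_terms and spec.grouping and "_offset" not in data.columns:
            keys = list(spec.grouping) + [spec.response]
            grouped = data.groupby(keys, sort=True).size().reset_index(name="_wt")
            if len(grouped) < 0.8 * len(data):
                data = grouped
                self.weights = grouped["_wt"].to_numpy(dtype=float)
        self.y = data[spec.response].to_numpy(dtype=float)
        self.n = len(self.y)
        cols = [np.ones(self.n)]
        self.coef_names = ["(Intercept)"]
        for t in spec.fixed_terms:
            cols.append(data[t].to_numpy(dtype=float))
            self.coef_names.append(t)
        self.X = np.column_stack(cols)
        self.p = self.X.shape[1]
        self.group_sizes: list[int] = []
        zblocks = []
        for gname in spec.grouping:
            codes, levels = pd.factorize(data[gname], sort=True)
            q = len(levels)
            self.group_sizes.append(q)
            zblocks.append(
                sparse.csr_matrix(
                    (np.ones(self.n), (np.arange(self.n), codes)), shape=(self.n, q)
                )
            )
        self.Z = sparse.hstack(zblocks, format="csr") if zblocks else None
        self.q = sum(self.group_sizes)
        self.B = (
            sparse.hstack([sparse.csr_matrix(self.X), self.Z], format="csr")
            if self.Z is not None
            else sparse.csr_matrix(self.X)
        )
        self.BT = self.B.T.tocsr()
        self._const = _family_const(spec.family, self.y, spec.trials)
        self._family = _FAMILIES[spec.family]
        self._warm: np.ndarray | None = None

    def _eval(self, eta, y, trials, phi):
        ll, g, w = self._family(eta, y, trials, phi, self._const)
        if self.weights is not None:
            return ll * self.weights, g * self.weights, w * self.weights
        return ll, g, w

    # penalty vector over (beta, u, v) for given sigmas
    def _penalty(self, sigmas: np.ndarray) -> np.ndarray:
        pen = np.zeros(self.p + self.q)
        offset = self.p
        for sd, q in zip(sigmas, self.group_sizes):
            pen[offset : offset + q] = 1.0 / sd**2
            offset += q
        return pen

    def _newton(
        self,
        pen: np.ndarray,
        phi: float | None,
        zeta0: np.ndarray,
        offset: np.ndarray | float = 0.0,
        B: sparse.csr_matrix | None = None,
        max_iter: int = 80,
    ):
        """Damped Newton ascent of the joint penalized log-likelihood."""
        B = self.B if B is None else B
        BT = B.T.tocsr()
        ridge = np.full(B.shape[1], _RIDGE)
        ridge[pen > 0] = 0.0
        zeta = zeta0.copy()
        eta = offset + B @ zeta
        ll, g, w = self._eval(eta, self.y, self.spec.trials, phi)
        f = ll.sum() - 0.5 * np.sum(pen * zeta**2)
        converged = False
        for _ in range(max_iter):
            grad = BT @ g - pen * zeta
            gnorm = np.max(np.abs(grad))
            if gnorm < 1e-9 * (1.0 + abs(f)):
                converged = True
                break
            H = (BT @ sparse.diags(w) @ B) + sparse.diags(pen + ridge)
            try:
                delta = splu(H.tocsc()).solve(grad)
            except RuntimeError:
                delta = splu((H + sparse.diags(np.full(B.shape[1], 1e-6))).tocsc()).solve(grad)
            step = 1.0
            while step > 1e-12:
                z2 = zeta + step * delta
                eta2 = offset + B @ z2
                ll2, g2, w2 = self._eval(eta2, self.y, self.spec.trials, phi)
                f2 = ll2.sum() - 0.5 * np.sum(pen * z2**2)
                if np.isfinite(f2) and f2 >= f - 1e-12 * (1.0 + abs(f)):
                    break
                step *= 0.5
            improved = f2 - f
            zeta, f, ll, g, w = z2, f2, ll2, g2, w2
            if improved < 1e-10 * (1.0 + abs(f)):
                converged = True
                break
        return zeta, f, ll, g, w, converged

    def marginal_loglik(self, theta: np.ndarray, warm: bool = True) -> float:
        """Profiled Laplace marginal log-likelihood at variance parameters
        theta = (log sigma per group [, log phi])."""
        n_g = len(self.group_sizes)
        sigmas = np.exp(theta[:n_g])
        phi = float(np.exp(theta[n_g])) if self.spec.has_dispersion else None
        pen = self._penalty(sigmas)
        zeta0 = (
            self._warm
            if (warm and self._warm is not None)
            else np.zeros(self.p + self.q)
        )
        zeta, f, ll, g, w, _ = self._newton(pen, phi, zeta0)
        self._warm = zeta
        return self._laplace_value(zeta, f, w, sigmas, pen)

    def _laplace_value(self, zeta, f, w, sigmas, pen) -> float:
        if self.q == 0:
            return f
        Haa = (self.Z.T @ sparse.diags(w) @ self.Z) + sparse.diags(pen[self.p :])
        logdet = _sparse_logdet(Haa.tocsc())
        pen_term = sum(q * np.log(sd) for sd, q in zip(sigmas, self.group_sizes))
        return f - pen_term - 0.5 * logdet


def _sparse_logdet(A: sparse.csc_matrix) -> float:
    if A.shape[0] == 1:
        return float(np.log(A[0, 0]))
    lu = splu(A)
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def laplace_loglik(
    spec: ModelSpec,
    data: pd.DataFrame,
    beta: np.ndarray,
    sigmas: dict[str, float] | None = None,
    phi: float | None = None,
) -> float:
    """Laplace-approximated marginal log-likelihood at the given parameters.

    ``beta`` is the fixed-effect vector (intercept first, then
    ``spec.fixed_terms`` order).  With every sigma zero the random effects
    vanish and the exact fixed-effect GLM log-likelihood is returned.
    """
    sigmas = sigmas or {}
    prob = _Problem(spec, data)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (prob.p,):
        raise ValueError(f"beta must have length {prob.p}")
    sd = np.array([float(sigmas.get(g, 0.0)) for g in spec.grouping])
    offset = prob.X @ beta
    if prob.q == 0 or np.all(sd == 0):
        ll, _, _ = prob._eval(offset, prob.y, spec.trials, phi)
        return float(ll.sum())
    if np.any(sd == 0):
        raise ValueError("mixed zero/non-zero sigmas are not supported; drop the group instead")
    pen = 1.0 / np.repeat(sd**2, prob.group_sizes)
    zeta, f, ll, g, w, converged = prob._newton(pen, phi, np.zeros(prob.q), offset=offset, B=prob.Z)
    if not converged:
        raise RuntimeError(f"inner Newton failed to converge (objective {f})")
    Haa = (prob.Z.T @ sparse.diags(w) @ prob.Z) + sparse.diags(pen)
    logdet = _sparse_logdet(Haa.tocsc())
    pen_term = sum(q * np.log(s) for s, q in zip(sd, prob.group_sizes))
    return float(f - pen_term - 0.5 * logdet)


def fit_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    start: np.ndarray | None = None,
    seed: int = 0,
    refine_beta: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of the mixed model by Laplace approximation.

    Two stages: first the outer quasi-Newton optimization runs over the
    log variance components (and log dispersion) with the fixed effects
    profiled inside the inner Newton step (fast, but it neglects the
    dependence of the Laplace log-determinant on beta); then, unless
    ``refine_beta`` is disabled, the exact Laplace objective is
    re-maximized jointly over (beta, log sigma, log phi) from that
    solution, which removes the small profiling bias in the fixed
    effects.  Three jittered restarts are attempted on non-convergence.
    A sigma estimated at the lower boundary is reported as
    converged-at-boundary, and any |coefficient| > 15 on the link scale
    raises a separation warning.
    """
    prob = _Problem(spec, data)
    n_g = len(prob.group_sizes)
    n_theta = n_g + (1 if spec.has_dispersion else 0)
    warn: list[str] = []

    if n_theta == 0:
        # pure GLM: single Newton pass over beta
        zeta, f, ll, g, w, conv = prob._newton(np.zeros(prob.p), None, np.zeros(prob.p))
        return _package_fit(prob, np.array([]), zeta, f, conv, warn)

    if start is not None:
        theta0 = np.asarray(start, dtype=float)
    else:
        theta0 = _moment_start(prob)

    bounds = [( _SIGMA_LOG_FLOOR, 4.0)] * n_g + (
        [(-4.0, 16.0)] if spec.has_dispersion else []
    )

    def objective(theta):
        return -prob.marginal_loglik(theta)

    # stage-1 tolerances are modest: the refinement stage (or, without it,
    # the flatness of the surface at this scale) makes tighter ones moot
    def run(theta_start):
        return optimize.minimize(
            objective,
            np.clip(theta_start, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-9, "gtol": 1e-6, "eps": 1e-5, "maxiter": 200},
        )

    rng = np.random.default_rng(seed)
    best = run(theta0)
    # the log-sigma floor is a flat corner of the surface; escape it and
    # retry (jittered) if the first run failed or collapsed every component
    sigma_floor = n_g > 0 and np.all(best.x[:n_g] <= _SIGMA_LOG_FLOOR + 1e-6)
    started_above = n_g == 0 or np.any(theta0[:n_g] > _SIGMA_LOG_FLOOR + 0.5)
    if not best.success or (sigma_floor and started_above):
        for attempt in range(3):
            alt = theta0 + rng.normal(0, 0.4, size=n_theta) + 0.3
            res = run(alt)
            if res.fun < best.fun - 1e-7:
                best = res
            if best.success and not np.all(best.x[:n_g] <= _SIGMA_LOG_FLOOR + 1e-6):
                break
            warn.append(f"outer optimizer restart {attempt + 1}")
    theta_hat = best.x
    # final inner solve at the optimum
    loglik = prob.marginal_loglik(theta_hat)
    zeta = prob._warm
    converged = bool(best.success)
    if refine_beta and prob.q > 0:
        theta_hat, zeta, loglik, ok = _refine_joint(prob, theta_hat, zeta, bounds)
        converged = converged and ok
    return _package_fit(prob, theta_hat, zeta, loglik, converged, warn, data=data)


def _refine_joint(prob, theta0, zeta0, theta_bounds):
    """Maximize the exact Laplace objective jointly over (beta, theta).

    The inner Newton runs over the random effects only, with X beta as an
    offset, so the log-determinant's beta-dependence enters the outer
    gradient instead of being ignored.
    """
    p, n_g = prob.p, len(prob.group_sizes)
    state = {"a": zeta0[p:].copy()}

    def obj(x):
        beta, theta = x[:p], x[p:]
        sigmas = np.exp(theta[:n_g])
        phi = float(np.exp(theta[n_g])) if prob.spec.has_dispersion else None
        offset = prob.X @ beta
        pen = 1.0 / np.repeat(np.maximum(sigmas, 1e-12) ** 2, prob.group_sizes)
        a, f, ll, g, w, _ = prob._newton(pen, phi, state["a"], offset=offset, B=prob.Z)
        state["a"] = a
        Haa = (prob.Z.T @ sparse.diags(w) @ prob.Z) + sparse.diags(pen)
        logdet = _sparse_logdet(Haa.tocsc())
        pen_term = sum(q * np.log(sd) for sd, q in zip(sigmas, prob.group_sizes))
        return -(f - pen_term - 0.5 * logdet)

    x0 = np.concatenate([zeta0[:p], theta0])
    bounds = [(None, None)] * p + list(theta_bounds)
    res = optimize.minimize(
        x0=x0,
        fun=obj,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-11, "gtol": 1e-6, "eps": 1e-5, "maxiter": 200},
    )
    loglik = -obj(res.x)  # re-evaluate so the inner state matches the optimum
    beta, theta = res.x[:p], res.x[p:]
    zeta = np.concatenate([beta, state["a"]])
    prob._warm = zeta
    return theta, zeta, float(loglik), bool(res.success)


def _moment_start(prob) -> np.ndarray:
    """Method-of-moments starting values for the variance parameters.

    Splits the apparent latent heterogeneity unevenly between the grouping
    factors (to break symmetry) and, for the beta-binomial, inverts the
    Morris variance ratio for a dispersion start.
    """
    spec = prob.spec
    n_g = len(spec.grouping)
    y = prob.y
    wt = prob.weights
    mean = max(float(np.average(y, weights=wt)), 1e-6)
    var = float(np.average((y - mean) ** 2, weights=wt)) if len(y) > 1 else mean
    if spec.family == "poisson":
        # lognormal-Poisson: var = m + m^2 (e^{s^2} - 1)
        s2 = np.log1p(max(var - mean, 0.0) / mean**2)
    else:
        k = float(spec.trials)
        mu = min(max(mean / k, 1e-4), 1 - 1e-4)
        # latent logit-scale heterogeneity from between-unit spread of rates
        s2 = max(var / (k * mu * (1 - mu)) - 1.0, 0.0) / (k * mu * (1 - mu))
    s = float(np.clip(np.sqrt(max(s2, 1e-4)), 0.05, 1.5))
    theta0 = np.empty(n_g + (1 if spec.has_dispersion else 0))
    scale = [0.8, 0.4, 0.3]
    for j in range(n_g):
        theta0[j] = np.log(max(s * scale[min(j, 2)], 0.05))
    if spec.has_dispersion:
        k = float(spec.trials)
        mu = min(max(mean / k, 1e-4), 1 - 1e-4)
        r = var / (k * mu * (1 - mu))
        phi0 = (k - r) / (r - 1.0) if 1.02 < r < k * 0.98 else 50.0 * k
        theta0[n_g] = np.log(np.clip(phi0, 2.0, 1e5))
    return theta0


def _package_fit(prob, theta, zeta, loglik, converged, warn, data=None) -> FitResult:
    spec = prob.spec
    n_g = len(prob.group_sizes)
    sigmas = np.exp(theta[:n_g]) if n_g else np.array([])
    phi = float(np.exp(theta[n_g])) if spec.has_dispersion else None
    beta = zeta[: prob.p]
    eta_fixed = prob.X @ beta

    flagged = [n for n, b in zip(prob.coef_names, beta) if abs(b) > _SEPARATION_THRESHOLD]
    if flagged:
        warn.append(f"possible separation: inflated coefficient(s) {flagged}")

    # Wald covariance of beta: beta block of the inverse joint Hessian
    pen = prob._penalty(sigmas) if n_g else np.zeros(prob.p)
    eta = prob.B @ zeta
    _, _, w = prob._eval(eta, prob.y, spec.trials, phi)
    H = (prob.BT @ sparse.diags(w) @ prob.B) + sparse.diags(
        pen + np.where(pen > 0, 0.0, _RIDGE)
    )
    lu = splu(H.tocsc())
    rhs = np.zeros((prob.p + prob.q, prob.p))
    rhs[: prob.p, :] = np.eye(prob.p)
    cov_beta = np.column_stack([lu.solve(rhs[:, j]) for j in range(prob.p)])[: prob.p, :]
    se_beta = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    z = norm.ppf(0.975)

    coefficients = dict(zip(prob.coef_names, beta.tolist()))
    se = dict(zip(prob.coef_names, se_beta.tolist()))
    wald_ci = {
        n: (b - z * s, b + z * s) for n, b, s in zip(prob.coef_names, beta, se_beta)
    }

    boundary = []
    sigma_d: dict[str, float] = {}
    sigma_ci: dict[str, tuple[float, float]] = {}
    phi_ci = None
    if n_g or spec.has_dispersion:
        # SEs of theta from the numeric Hessian of the profiled Laplace loglik
        theta_se = _numeric_theta_se(prob, theta)
        for j, g in enumerate(spec.grouping):
            sigma_d[g] = float(sigmas[j])
            if theta[j] <= _SIGMA_LOG_FLOOR + 1e-6:
                boundary.append(f"sigma_{g}")
                sigma_ci[g] = (0.0, float(sigmas[j]))
            else:
                h = z * theta_se[j]
                if not np.isfinite(h):
                    sigma_ci[g] = (0.0, np.inf)
                else:
                    h = min(h, 50.0)
                    sigma_ci[g] = (float(sigmas[j] * np.exp(-h)), float(sigmas[j] * np.exp(h)))
        if spec.has_dispersion:
            # with tens of trials at most, phi beyond ~e^9 is numerically
            # binomial and the profile in log phi is flat: call it boundary
            if theta[n_g] >= 9.0:
                boundary.append("phi")
                warn.append("dispersion at upper bound: no overdispersion beyond binomial")
                phi_ci = (phi, np.inf)
            else:
                h = z * theta_se[n_g]
                phi_ci = (float(phi * np.exp(-h)), float(phi * np.exp(h)))

    n_params = prob.p + n_g + (1 if spec.has_dispersion else 0)
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(prob.n_total)
    return FitResult(
        spec=spec,
        coefficients=coefficients,
        se=se,
        wald_ci=wald_ci,
        sigma=sigma_d,
        sigma_ci=sigma_ci,
        phi=phi,
        phi_ci=phi_ci,
        loglik=float(loglik),
        aic=float(aic),
        bic=float(bic),
        n_obs=prob.n_total,
        n_params=n_params,
        converged=converged,
        boundary=boundary,
        warnings=warn,
        flagged=flagged,
        eta_fixed=eta_fixed,
        _problem=prob,
        _theta=theta,
    )


def _numeric_theta_se(prob, theta, h: float = 1e-3) -> np.ndarray:
    d = len(theta)
    se = np.full(d, np.nan)
    f0 = prob.marginal_loglik(theta)
    for j in range(d):
        if theta[j] <= _SIGMA_LOG_FLOOR + 1e-6:
            continue
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        second = (prob.marginal_loglik(tp) - 2 * f0 + prob.marginal_loglik(tm)) / h**2
        if second < 0:
            se[j] = 1.0 / np.sqrt(-second)
    return se


# ---------------------------------------------------------------------------
# profile confidence intervals
# ---------------------------------------------------------------------------


def _profile_value(fit: FitResult, parameter: str, value: float, data: pd.DataFrame) -> float:
    """Maximized log-likelihood with one parameter held fixed."""
    spec = fit.spec
    prob = fit._problem
    n_g = len(spec.grouping)
    if parameter in fit.coefficients:
        # move the fixed column into an offset and refit the rest
        if parameter == "(Intercept)":
            col = np.ones(len(data))
        else:
            col = data[parameter].to_numpy(dtype=float)
        offset = col * value
        keep = [n for n in prob.coef_names if n != parameter]
        work = data.copy()
        work["_offset"] = offset
        return _fit_with_offset(spec, work, keep, fit._theta)
    # variance / dispersion parameter
    names = [f"sigma_{g}" for g in spec.grouping] + (["phi"] if spec.has_dispersion else [])
    if parameter not in names:
        raise KeyError(parameter)
    j = names.index(parameter)
    fixed_log = np.log(value) if value > 0 else _SIGMA_LOG_FLOOR
    free = [i for i in range(len(fit._theta)) if i != j]
    if not free:
        theta = np.array([fixed_log])
        return prob.marginal_loglik(theta)

    def obj(tfree):
        theta = np.empty(len(fit._theta))
        theta[free] = tfree
        theta[j] = fixed_log
        return -prob.marginal_loglik(theta)

    res = optimize.minimize(
        obj,
        fit._theta[free],
        method="L-BFGS-B",
        bounds=[(_SIGMA_LOG_FLOOR, 16.0)] * len(free),
        options={"ftol": 1e-11, "eps": 1e-5},
    )
    return -res.fun


def _fit_with_offset(spec, data, fixed_terms, theta_start):
    """Refit with a fixed offset column ``_offset`` and reduced fixed terms."""
    sub = ModelSpec(
        family=spec.family,
        response=spec.response,
        fixed_terms=tuple(t for t in fixed_terms if t != "(Intercept)"),
        grouping=spec.grouping,
        trials=spec.trials,
    )
    prob = _Problem(sub, data)
    offset = data["_offset"].to_numpy(dtype=float)
    include_intercept = "(Intercept)" in fixed_terms
    if not include_intercept:
        prob.X = prob.X[:, 1:]
        prob.coef_names = prob.coef_names[1:]
        prob.p -= 1
        prob.B = (
            sparse.hstack([sparse.csr_matrix(prob.X), prob.Z], format="csr")
            if prob.Z is not None
            else sparse.csr_matrix(prob.X)
        )
        prob.BT = prob.B.T.tocsr()

    n_g = len(sub.grouping)

    def obj(theta):
        sigmas = np.exp(theta[:n_g])
        phi = float(np.exp(theta[n_g])) if sub.has_dispersion else None
        pen = prob._penalty(sigmas)
        zeta0 = prob._warm if prob._warm is not None else np.zeros(prob.p + prob.q)
        zeta, f, ll, g, w, _ = prob._newton(pen, phi, zeta0, offset=offset)
        prob._warm = zeta
        return -prob._laplace_value(zeta, f, w, sigmas, pen)

    if len(theta_start) == 0:
        zeta, f, ll, g, w, _ = prob._newton(np.zeros(prob.p), None, np.zeros(prob.p), offset=offset)
        return f
    res = optimize.minimize(
        obj,
        theta_start,
        method="L-BFGS-B",
        bounds=[(_SIGMA_LOG_FLOOR, 16.0)] * len(theta_start),
        options={"ftol": 1e-11, "eps": 1e-5},
    )
    return -res.fun


def profile_ci(
    fit: FitResult, parameter: str, data: pd.DataFrame, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood confidence interval by bisection on the
    likelihood-ratio statistic against the chi-square(1) quantile."""
    if not fit.converged:
        raise RuntimeError("profile CI requires a converged fit")
    crit = chi2.ppf(level, 1)
    if parameter in fit.coefficients:
        est = fit.coefficients[parameter]
        scale = max(fit.se.get(parameter, 0.5), 1e-3)
        lower_floor = None
    elif parameter.startswith("sigma_"):
        g = parameter[len("sigma_") :]
        est = fit.sigma[g]
        lo, hi = fit.sigma_ci[g]
        scale = max((hi - lo) / 4.0, 0.05 * max(est, 0.05))
        lower_floor = 0.0
    elif parameter == "phi":
        est = fit.phi
        scale = 0.25 * est
        lower_floor = 0.0
    else:
        raise KeyError(parameter)

    def lr(value):
        return 2.0 * (fit.loglik - _profile_value(fit, parameter, value, data)) - crit

    def search(direction: int) -> float:
        step = scale
        inner = est
        for _ in range(40):
            cand = est + direction * step
            if lower_floor is not None and cand <= lower_floor:
                if lr(lower_floor + 1e-9) < 0:
                    return lower_floor
                cand = lower_floor + 1e-9
                return optimize.brentq(lr, cand, inner, xtol=1e-6 * max(1.0, abs(est)))
            val = lr(cand)
            if val > 0:
                return optimize.brentq(lr, *sorted((inner, cand)), xtol=1e-6 * max(1.0, abs(est)))
            inner = cand
            step *= 2.0
        raise RuntimeError(f"profile for {parameter} did not cross the threshold")

    return search(-1), search(+1)


# ---------------------------------------------------------------------------
# variance decomposition
# ---------------------------------------------------------------------------


def variance_decomposition(fit: FitResult) -> VarianceDecomposition:
    """Latent-scale marginal/conditional R-squared and adjusted ICC.

    var_fixed is the variance of the fixed linear predictor across rows;
    var_random sums the squared random-intercept SDs; the residual variance
    is family-specific: the log-normal approximation ln(1/lambda + 1) for
    the Poisson log link (lambda the marginal expected count) and pi^2/3
    for logit links.
    """
    if not fit.sigma:
        raise ValueError("variance decomposition requires random effects")
    var_fixed = float(np.var(fit.eta_fixed))
    var_random = float(sum(sd**2 for sd in fit.sigma.values()))
    if fit.spec.family == "poisson":
        lam = float(np.exp(np.mean(fit.eta_fixed) + 0.5 * var_random))
        var_resid = float(np.log(1.0 / lam + 1.0))
    elif fit.spec.family in ("binomial", "betabinom"):
        var_resid = np.pi**2 / 3.0
    else:  # pragma: no cover
        raise ValueError(f"no residual-variance approximation for {fit.spec.family}")
    total = var_fixed + var_random + var_resid
    return VarianceDecomposition(
        marginal_r2=var_fixed / total,
        conditional_r2=(var_fixed + var_random) / total,
        adjusted_icc=var_random / (var_random + var_resid),
    )


# ---------------------------------------------------------------------------
# dense Gauss-Hermite oracle (verification only)
# ---------------------------------------------------------------------------


def quadrature_loglik(
    spec: ModelSpec,
    data: pd.DataFrame,
    beta: np.ndarray,
    sigmas: dict[str, float],
    phi: float | None = None,
    nodes: int = 25,
) -> float:
    """Dense tensor-product Gauss-Hermite marginal log-likelihood.

    Enumerates the full grid over every random-effect level, so it is
    limited to at most six levels in total.  Independent of the Laplace
    code path by construction.
    """
    y = data[spec.response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(y))] + [data[t].to_numpy(dtype=float) for t in spec.fixed_terms]
    )
    eta0 = X @ np.asarray(beta, dtype=float)
    fam = _FAMILIES[spec.family]

    codes = []
    counts = []
    sds = []
    for g in spec.grouping:
        c, levels = pd.factorize(data[g], sort=True)
        codes.append(c)
        counts.append(len(levels))
        sds.append(float(sigmas.get(g, 0.0)))
    qtot = sum(counts)
    if qtot > 6:
        raise ValueError("quadrature oracle limited to 6 random-effect levels")
    x_nodes, w_nodes = np.polynomial.hermite.hermgauss(nodes)
    logw = np.log(w_nodes) - 0.5 * np.log(np.pi)

    # dimension index of each (grouping factor, level)
    offsets = np.concatenate([[0], np.cumsum(counts)])[:-1]
    grid_shape = (nodes,) * qtot
    total = np.zeros(grid_shape)

    if len(codes) == 1:
        cells = {(l,): np.flatnonzero(codes[0] == l) for l in range(counts[0])}
    else:
        cells = {}
        for l in range(counts[0]):
            for m in range(counts[1]):
                rows = np.flatnonzero((codes[0] == l) & (codes[1] == m))
                if len(rows):
                    cells[(l, m)] = rows

    for key, rows in cells.items():
        # per-cell log-likelihood table over the node grid of its dims
        if len(key) == 1:
            re = np.sqrt(2.0) * sds[0] * x_nodes
            eta = eta0[rows][None, :] + re[:, None]
            ll, _, _ = fam(eta, y[rows][None, :], spec.trials, phi)
            table = ll.sum(axis=1)
            shape = [1] * qtot
            shape[offsets[0] + key[0]] = nodes
            total = total + table.reshape(shape)
        else:
            re_u = np.sqrt(2.0) * sds[0] * x_nodes
            re_v = np.sqrt(2.0) * sds[1] * x_nodes
            eta = eta0[rows][None, None, :] + re_u[:, None, None] + re_v[None, :, None]
            ll, _, _ = fam(eta, y[rows][None, None, :], spec.trials, phi)
            table = ll.sum(axis=2)  # (nodes, nodes)
            shape = [1] * qtot
            shape[offsets[0] + key[0]] = nodes
            shape[offsets[1] + key[1]] = nodes
            total = total + table.reshape(shape)

    for d in range(qtot):
        shape = [1] * qtot
        shape[d] = nodes
        total = total + logw.reshape(shape)
    return float(logsumexp(total))
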