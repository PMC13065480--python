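"""GLMM engine: Laplace correctness, invariances, intervals, decomposition."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alepanel import (
    FrailtyParams,
    ModelSpec,
    couple_households,
    fit_glmm,
    laplace_loglik,
    profile_ci,
    quadrature_loglik,
    simulate_frailty_panel,
    variance_decomposition,
)


@pytest.fixture(scope="module")
def tiny_crossed():
    """3 individuals x 2 households x 3 years of Poisson counts."""
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "individual": np.repeat([0, 1, 2], 3),
            "household": [0, 0, 0, 0, 1, 1, 1, 1, 1],
            "y": rng.poisson(1.2, 9),
        }
    )


@pytest.fixture(scope="module")
def frailty_data():
    panel = simulate_frailty_panel(
        FrailtyParams(0.8, 0.4, 0.3), couple_households(400, 4), 20, seed=21
    )
    return panel.data.rename(columns={"id": "individual", "hh_id": "household", "count": "y"})


POISSON = ModelSpec(family="poisson")
POISSON_GLM = ModelSpec(family="poisson", grouping=())


class TestLaplaceLoglik:
    def test_sigma_zero_equals_glm_loglik(self, tiny_crossed):
        beta = [0.25]
        lap = laplace_loglik(POISSON, tiny_crossed, beta, {"individual": 0.0, "household": 0.0})
        exact = stats.poisson.logpmf(tiny_crossed["y"], np.exp(0.25)).sum()
        assert lap == pytest.approx(exact, abs=1e-8)

    @pytest.mark.parametrize(
        "beta,si,sh", [(0.2, 0.4, 0.3), (-0.3, 0.8, 0.2), (0.0, 0.15, 0.6)]
    )
    def test_agrees_with_dense_quadrature(self, tiny_crossed, beta, si, sh):
        sig = {"individual": si, "household": sh}
        lap = laplace_loglik(POISSON, tiny_crossed, [beta], sig)
        quad = quadrature_loglik(POISSON, tiny_crossed, [beta], sig, nodes=31)
        assert lap == pytest.approx(quad, abs=0.1)

    def test_binomial_agrees_with_quadrature(self, tiny_crossed):
        data = tiny_crossed.assign(y=(tiny_crossed["y"] > 0).astype(int))
        spec = ModelSpec(family="binomial", trials=1)
        sig = {"individual": 0.5, "household": 0.4}
        lap = laplace_loglik(spec, data, [-0.2], sig)
        quad = quadrature_loglik(spec, data, [-0.2], sig, nodes=31)
        assert lap == pytest.approx(quad, abs=0.1)


class TestFitGlmm:
    def test_intercept_only_poisson_mle_is_mean(self):
        data = pd.DataFrame({"y": [2, 0, 1, 1]})
        fit = fit_glmm(POISSON_GLM, data)
        assert np.exp(fit.coefficients["(Intercept)"]) == pytest.approx(1.0, abs=1e-6)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.bic == pytest.approx(-2 * fit.loglik + fit.n_params * np.log(4))

    def test_2x2_logistic_or_closed_form(self):
        # a=10, b=5, c=2, d=20 -> OR = ad/bc = 20
        rows = []
        for x, y, n in [(1, 1, 10), (1, 0, 5), (0, 1, 2), (0, 0, 20)]:
            rows += [{"x": x, "y": y}] * n
        data = pd.DataFrame(rows)
        spec = ModelSpec(family="binomial", fixed_terms=("x",), grouping=(), trials=1)
        fit = fit_glmm(spec, data)
        assert np.exp(fit.coefficients["x"]) == pytest.approx(20.0, rel=1e-4)

    def test_zero_covariate_leaves_loglik_unchanged(self, frailty_data):
        base = fit_glmm(POISSON, frailty_data, seed=1)
        data = frailty_data.assign(z=0.0)
        spec = ModelSpec(family="poisson", fixed_terms=("z",))
        # exact objective invariance: a zero column contributes nothing
        l_aug = laplace_loglik(
            spec, data, [base.coefficients["(Intercept)"], 1.23], dict(base.sigma)
        )
        l_base = laplace_loglik(
            POISSON, frailty_data, [base.coefficients["(Intercept)"]], dict(base.sigma)
        )
        assert l_aug == pytest.approx(l_base, abs=1e-6)
        # and the maximized fits agree to optimizer precision
        aug = fit_glmm(spec, data, seed=1)
        assert aug.loglik == pytest.approx(base.loglik, abs=1e-3)

    def test_covariate_scaling_invariance(self, frailty_data):
        rng = np.random.default_rng(2)
        data = frailty_data.assign(x=rng.normal(size=len(frailty_data)))
        spec = ModelSpec(family="poisson", fixed_terms=("x",))
        f1 = fit_glmm(spec, data, seed=1)
        # the objective itself is exactly invariant: evaluating at the
        # rescaled coefficient on rescaled data reproduces the loglik
        beta = [f1.coefficients["(Intercept)"], f1.coefficients["x"] / 10]
        sig = dict(f1.sigma)
        l_scaled = laplace_loglik(spec, data.assign(x=data["x"] * 10), beta, sig)
        l_orig = laplace_loglik(
            spec, data, [f1.coefficients["(Intercept)"], f1.coefficients["x"]], sig
        )
        assert l_scaled == pytest.approx(l_orig, abs=1e-6)
        # and the fit agrees to optimizer precision
        f10 = fit_glmm(spec, data.assign(x=data["x"] * 10), seed=1)
        assert f10.coefficients["x"] * 10 == pytest.approx(f1.coefficients["x"], abs=2e-4)
        assert f10.loglik == pytest.approx(f1.loglik, abs=1e-3)

    def test_frailty_nests_bad_luck(self, frailty_data):
        glm = fit_glmm(POISSON_GLM, frailty_data)
        mixed = fit_glmm(POISSON, frailty_data, seed=1)
        assert mixed.loglik >= glm.loglik - 1e-6

    def test_poisson_truth_puts_sigma_at_boundary(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            {
                "individual": np.repeat(np.arange(200), 10),
                "household": np.repeat(np.arange(200) // 2, 10),
                "y": rng.poisson(0.9, 2000),
            }
        )
        fit = fit_glmm(POISSON, data, seed=1)
        assert all(sd < 0.08 for sd in fit.sigma.values())

    def test_betabinom_large_phi_converges_to_binomial(self, tiny_crossed):
        data = tiny_crossed.assign(y=(tiny_crossed["y"] > 0).astype(int))
        bb = ModelSpec(family="betabinom", trials=1, grouping=())
        bn = ModelSpec(family="binomial", trials=1, grouping=())
        ll_bb = laplace_loglik(bb, data, [0.1], phi=1e6)
        ll_bn = laplace_loglik(bn, data, [0.1])
        assert ll_bb == pytest.approx(ll_bn, abs=1e-3)

    def test_binomial_truth_sends_dispersion_to_bound(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(
            {
                "individual": np.repeat(np.arange(300), 8),
                "household": np.repeat(np.arange(150), 16),
                "y": rng.binomial(6, 0.2, 2400),
            }
        )
        fit = fit_glmm(ModelSpec(family="betabinom", trials=6), data, seed=1)
        assert "phi" in fit.boundary
        assert any("overdispersion" in w for w in fit.warnings)

    def test_separation_flagged(self):
        # perfectly separated logistic fit
        data = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1], "y": [0, 0, 0, 1, 1, 1]})
        spec = ModelSpec(family="binomial", fixed_terms=("x",), grouping=(), trials=1)
        fit = fit_glmm(spec, data)
        assert "x" in fit.flagged


class TestAgreementWithReferenceImplementation:
    def test_matches_glmmtmb_on_small_fixture(self, tmp_path):
        """Cross-check against glmmTMB (R) on one small crossed Poisson fit."""
        panel = simulate_frailty_panel(
            FrailtyParams(0.9, 0.35, 0.3), couple_households(150, 3), 10, seed=22
        )
        data = panel.data.rename(columns={"id": "individual", "hh_id": "household", "count": "y"})
        fit = fit_glmm(POISSON, data, seed=1)
        csv = tmp_path / "d.csv"
        data[["individual", "household", "y"]].to_csv(csv, index=False)
        script = tmp_path / "m.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(glmmTMB))
                d <- read.csv("{csv}")
                m <- glmmTMB(y ~ 1 + (1|individual) + (1|household),
                             family = poisson, data = d)
                v <- VarCorr(m)$cond
                cat(fixef(m)$cond[[1]],
                    attr(v$individual, "stddev"),
                    attr(v$household, "stddev"),
                    as.numeric(logLik(m)), sep = ",")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, si, sh, ll = map(float, out.stdout.strip().split(","))
        assert fit.coefficients["(Intercept)"] == pytest.approx(b0, abs=0.01)
        assert fit.sigma["individual"] == pytest.approx(si, abs=0.02)
        assert fit.sigma["household"] == pytest.approx(sh, abs=0.02)
        assert fit.loglik == pytest.approx(ll, abs=0.5)


class TestProfileCI:
    @pytest.fixture(scope="class")
    def fit_and_data(self):
        panel = simulate_frailty_panel(
            FrailtyParams(0.9, 0.35, 0.3), couple_households(200, 4), 12, seed=23
        )
        data = panel.data.rename(columns={"id": "individual", "hh_id": "household", "count": "y"})
        return fit_glmm(POISSON, data, seed=1), data

    def test_profile_close_to_wald_in_regular_problem(self, fit_and_data):
        fit, data = fit_and_data
        lo, hi = profile_ci(fit, "(Intercept)", data)
        wlo, whi = fit.wald_ci["(Intercept)"]
        assert (hi - lo) == pytest.approx(whi - wlo, rel=0.05)
        assert lo < fit.coefficients["(Intercept)"] < hi

    def test_sigma_interval_contains_estimate(self, fit_and_data):
        fit, data = fit_and_data
        lo, hi = profile_ci(fit, "sigma_individual", data)
        assert lo < fit.sigma["individual"] < hi

    def test_boundary_sigma_has_zero_lower_endpoint(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(
            {
                "individual": np.repeat(np.arange(80), 10),
                "household": np.repeat(np.arange(40), 20),
                "y": rng.poisson(1.0, 800),
            }
        )
        fit = fit_glmm(POISSON, data, seed=1)
        lo, hi = profile_ci(fit, "sigma_household", data)
        assert lo == 0.0


class TestVarianceDecomposition:
    def test_intercept_only_marginal_r2_zero(self, frailty_data):
        fit = fit_glmm(POISSON, frailty_data, seed=1)
        dec = variance_decomposition(fit)
        assert dec.marginal_r2 == pytest.approx(0.0, abs=1e-12)
        assert dec.adjusted_icc == pytest.approx(dec.conditional_r2)
        assert 0 <= dec.marginal_r2 <= dec.conditional_r2 <= 1

    def test_zero_sigma_gives_zero_icc(self, frailty_data):
        fit = fit_glmm(POISSON, frailty_data, seed=1)
        fit.sigma = {"individual": 0.0, "household": 0.0}
        assert variance_decomposition(fit).adjusted_icc == 0.0

    def test_icc_increases_with_household_sd(self, frailty_data):
        fit = fit_glmm(POISSON, frailty_data, seed=1)
        base = variance_decomposition(fit).adjusted_icc
        fit.sigma = dict(fit.sigma, household=fit.sigma["household"] + 0.3)
        assert variance_decomposition(fit).adjusted_icc > base

    def test_requires_random_effects(self, frailty_data):
        fit = fit_glmm(POISSON_GLM, frailty_data)
        with pytest.raises(ValueError):
            variance_decomposition(fit)
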