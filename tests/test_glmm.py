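from __future__ import annotations

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from treemort.glmm import (
    BinomialMixedLogit,
    _Problem,
    _fit_conditional_mode,
    fit_glmm,
    laplace_loglik,
    standardize,
    wald_significance,
)

from _oracles import gauss_hermite_loglik, irls_logistic


def _simulate(n, qs, qg, alpha, beta, sigma_s, sigma_g, seed):
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, float))
    X = rng.standard_normal((n, len(beta)))
    sp = rng.integers(0, qs, n)
    gr = rng.integers(0, qg, n)
    us = rng.normal(0, sigma_s, qs)
    ug = rng.normal(0, sigma_g, qg)
    eta = alpha + X @ beta + us[sp] + ug[gr]
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return y, X, sp, gr


class TestStandardize:
    def test_two_point_example(self):
        z, mean, sd = standardize([0.0, 2.0])
        np.testing.assert_allclose(z, [-np.sqrt(0.5), np.sqrt(0.5)], rtol=1e-12)
        assert mean == 1.0 and sd == pytest.approx(np.sqrt(2.0))

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(100)
        z1, _, _ = standardize(v)
        z2, _, _ = standardize(z1)
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_constant_vector_raises_with_name(self):
        with pytest.raises(ValueError, match="soil_ph"):
            standardize(np.ones(10), name="soil_ph")


class TestWaldSignificance:
    def test_clearly_significant(self):
        assert wald_significance(0.5, 0.1)

    def test_zero_effect_not_significant(self):
        assert not wald_significance(0.0, 0.1)

    def test_boundary_is_strict(self):
        assert not wald_significance(1.96 * 0.1, 0.1)


class TestAgainstLogisticRegression:
    def test_pinned_zero_variances_match_irls(self):
        y, X, sp, gr = _simulate(2000, 10, 40, -1.0, [0.5, -0.3], 0.4, 0.3, 1)
        fit = fit_glmm(y, X, species=sp, grid=gr, fix_sigma=(0.0, 0.0))
        ref = irls_logistic(y, X)
        got = np.r_[fit.alpha, list(fit.beta.values())]
        np.testing.assert_allclose(got, ref, atol=1e-6)

    def test_null_data_intercept_near_zero(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 4000)
        fit = fit_glmm(y, None, species=rng.integers(0, 10, 4000),
                       grid=rng.integers(0, 10, 4000))
        assert abs(fit.alpha) < 3 * fit.alpha_se


class TestLaplaceAccuracy:
    def test_loglik_within_tenth_nat_of_quadrature(self):
        # small crossed design: 2 species x 3 grids, n = 180
        y, X, sp, gr = _simulate(180, 2, 3, -0.5, [0.4], 0.5, 0.3, 5)
        for alpha, beta, ss, sg in [
            (-0.5, [0.4], 0.5, 0.3),
            (0.0, [0.0], 0.3, 0.6),
            (-1.0, [0.8], 0.8, 0.2),
        ]:
            lap = laplace_loglik(y, X, sp, gr, alpha, beta, ss, sg)
            exact = gauss_hermite_loglik(y, X, sp, gr, alpha, np.asarray(beta), ss, sg,
                                         n_nodes=12)
            assert lap == pytest.approx(exact, abs=0.1), (alpha, beta, ss, sg)

    def test_penalized_objective_monotone_across_newton_iterations(self):
        y, X, sp, gr = _simulate(500, 5, 10, -1.0, [0.5], 0.5, 0.3, 3)
        prob = _Problem(y, X, sp, gr)
        res = _fit_conditional_mode(prob, 0.5, 0.3)
        trace = np.asarray(res["trace"])
        assert (np.diff(trace) >= -1e-9).all()
        assert res["converged"]


class TestParameterRecovery:
    def test_forward_simulation_recovery(self):
        # moderate-size crossed design; estimates averaged over replicates
        # should sit within two Monte-Carlo standard errors of the truth
        truth = {"alpha": -2.0, "beta": 0.5, "ss": 0.5, "sg": 0.3}
        ests = []
        for rep in range(10):
            y, X, sp, gr = _simulate(
                20_000, 40, 400, truth["alpha"], [truth["beta"]],
                truth["ss"], truth["sg"], 100 + rep,
            )
            fit = fit_glmm(y, X, species=sp, grid=gr)
            assert fit.converged
            ests.append([fit.alpha, fit.beta["x0"], fit.sigma_species, fit.sigma_grid])
        ests = np.asarray(ests)
        means = ests.mean(axis=0)
        mc_se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        for got, se, want in zip(means, mc_se, truth.values()):
            assert abs(got - want) < 2 * se + 1e-6, (got, want, se)

    def test_aic_bookkeeping(self):
        y, X, sp, gr = _simulate(1000, 8, 20, -1.0, [0.3, 0.1], 0.4, 0.3, 9)
        fit = fit_glmm(y, X, species=sp, grid=gr)
        assert fit.n_params == 2 + 1 + 2
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)

    def test_invariant_to_affine_covariate_rescaling(self):
        y, X, sp, gr = _simulate(1500, 6, 30, -1.5, [0.4], 0.5, 0.3, 11)
        z = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std(ddof=1)
        raw = 3.0 + 40.0 * X[:, 0]
        z2 = (raw - raw.mean()) / raw.std(ddof=1)
        f1 = fit_glmm(y, z[:, None], species=sp, grid=gr)
        f2 = fit_glmm(y, z2[:, None], species=sp, grid=gr)
        assert f1.beta["x0"] == pytest.approx(f2.beta["x0"], abs=1e-6)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)


class TestAgainstLme4:
    def test_matches_lme4_on_shared_fixture(self, tmp_path):
        """Coefficients, variance components and Laplace log-likelihood
        agree with R's reference mixed-model implementation."""
        y, X, sp, gr = _simulate(2000, 15, 50, -1.5, [0.5, -0.3], 0.5, 0.3, 0)
        csv = tmp_path / "fix.csv"
        pd.DataFrame({"y": y, "x1": X[:, 0], "x2": X[:, 1], "sp": sp, "gr": gr}).to_csv(
            csv, index=False
        )
        script = (
            f"d <- read.csv('{csv}');"
            "suppressMessages(library(lme4));"
            "m <- glmer(y ~ x1 + x2 + (1|sp) + (1|gr), data=d, family=binomial);"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep=',')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().split(",")]
        a_r, b1_r, b2_r, sg_r, ss_r, ll_r = vals  # VarCorr orders gr before sp
        fit = fit_glmm(y, X, species=sp, grid=gr)
        assert fit.alpha == pytest.approx(a_r, abs=0.02)
        assert fit.beta["x0"] == pytest.approx(b1_r, abs=0.02)
        assert fit.beta["x1"] == pytest.approx(b2_r, abs=0.02)
        assert fit.sigma_species == pytest.approx(ss_r, abs=0.03)
        assert fit.sigma_grid == pytest.approx(sg_r, abs=0.03)
        assert fit.loglik == pytest.approx(ll_r, abs=0.1)
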