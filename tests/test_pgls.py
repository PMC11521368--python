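"""The GLS core: estimates, profile likelihood, tests, coefficient tables."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import phylopgls as pg
from phylopgls.pgls import DegenerateFitError, PGLSError, gls_estimate

from conftest import random_tree


def explicit_inverse_gls(y, X, V):
    """Independent closed-form oracle: invert V explicitly."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    n, k = X.shape
    sigma2 = float(r @ Vi @ r) / n
    loglik = -0.5 * (
        n * np.log(2 * np.pi * sigma2) + np.linalg.slogdet(V)[1] + n
    )
    se = np.sqrt(np.diag(np.linalg.inv(XtViX)) * sigma2 * n / (n - k))
    return beta, se, sigma2, loglik


def random_instance(rng, n, k=2):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = rng.normal(size=k)
    tree = random_tree(rng, n)
    V = pg.bm_covariance(tree).values
    y = X @ beta + np.linalg.cholesky(V) @ rng.normal(size=n) * 0.5
    return y, X, V


class TestGLSEstimate:
    def test_identity_covariance_reduces_to_ols(self, rng):
        y, X, _ = random_instance(rng, 20, k=3)
        res = gls_estimate(y, X, np.eye(20))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res.beta, ols.params, atol=1e-10)
        np.testing.assert_allclose(res.se, ols.bse, atol=1e-10)

    def test_matches_explicit_inverse_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 13))
            y, X, V = random_instance(rng, n)
            res = gls_estimate(y, X, V)
            beta, se, sigma2, loglik = explicit_inverse_gls(y, X, V)
            np.testing.assert_allclose(res.beta, beta, atol=1e-8)
            np.testing.assert_allclose(res.se, se, atol=1e-8)
            assert res.sigma2 == pytest.approx(sigma2, abs=1e-8)
            assert res.loglik == pytest.approx(loglik, abs=1e-8)

    def test_perfect_fit_raises_degenerate(self, rng):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = X @ np.array([1.0, 2.0])
        with pytest.raises(DegenerateFitError):
            gls_estimate(y, X, np.eye(8))

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([np.ones(10), x, 2 * x])
        y = rng.normal(size=10)
        with pytest.raises(PGLSError, match="dup"):
            gls_estimate(y, X, np.eye(10), term_names=["int", "x", "dup"])


class TestFitPGLS:
    def test_brownian_statistics_identities(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        fit = pg.fit_pgls(data, default_spec, tree, kind="brownian")
        np.testing.assert_allclose(fit.t, fit.beta / fit.se, atol=1e-10)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k, abs=1e-12)
        assert fit.k == len(default_spec.terms) + 1  # coefficients + sigma^2
        assert ((fit.p >= 0) & (fit.p <= 1)).all()
        assert (fit.se > 0).all() and fit.sigma2 > 0

    def test_pagel_fixed_at_one_matches_brownian(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        bm = pg.fit_pgls(data, default_spec, tree, kind="brownian")
        pl = pg.fit_pgls(data, default_spec, tree, kind="pagel", fixed_parameter=1.0)
        assert pl.loglik == pytest.approx(bm.loglik, abs=1e-8)
        np.testing.assert_allclose(pl.beta, bm.beta, atol=1e-8)

    def test_pagel_fixed_at_zero_matches_ols(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        fit = pg.fit_pgls(data, default_spec, tree, kind="pagel", fixed_parameter=0.0)
        sub = data[[default_spec.response, *default_spec.predictors]].dropna()
        X = sm.add_constant(sub[list(default_spec.predictors)].to_numpy())
        ols = sm.OLS(sub[default_spec.response].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-8)

    def test_star_tree_equals_ols(self, rng):
        tree = pg.read_tree("(%s);" % ",".join(f"s{i}:1" for i in range(12)))
        x = rng.normal(size=12)
        y = 1.0 + 0.5 * x + rng.normal(size=12)
        data = pd.DataFrame({"x": x, "y": y}, index=tree.tips)
        fit = pg.fit_pgls(data, pg.ModelSpec("y", ("x",)), tree, kind="brownian")
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-8)
        np.testing.assert_allclose(fit.p, ols.pvalues, atol=1e-8)

    def test_lambda_recovery_under_iid_noise(self):
        # data generated with lambda=0 (tree-free noise) at n=100
        tree = pg.simulate_tree(100, seed=11)
        rng = np.random.default_rng(11)
        x = rng.normal(size=100)
        y = 2.0 + 0.5 * x + rng.normal(size=100)
        data = pd.DataFrame({"x": x, "y": y}, index=tree.tips)
        fit = pg.fit_pgls(data, pg.ModelSpec("y", ("x",)), tree, kind="pagel")
        assert fit.structure.parameter < 0.2

    def test_profile_maximum_beats_endpoints(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        fit = pg.fit_pgls(data, default_spec, tree, kind="pagel")
        at0 = pg.fit_pgls(data, default_spec, tree, kind="pagel", fixed_parameter=0.0)
        at1 = pg.fit_pgls(data, default_spec, tree, kind="pagel", fixed_parameter=1.0)
        assert fit.loglik >= at0.loglik - 1e-6
        assert fit.loglik >= at1.loglik - 1e-6

    def test_branch_length_scale_equivariance(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        fit1 = pg.fit_pgls(data, default_spec, tree, kind="brownian")
        scaled = tree.copy()
        for edge in scaled.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 7.5
        fit2 = pg.fit_pgls(data, default_spec, pg.Phylogeny(scaled.tree), kind="brownian")
        np.testing.assert_allclose(fit2.beta, fit1.beta, atol=1e-8)
        np.testing.assert_allclose(fit2.se, fit1.se, atol=1e-8)
        np.testing.assert_allclose(fit2.p, fit1.p, atol=1e-10)
        assert fit2.sigma2 == pytest.approx(fit1.sigma2 / 7.5, rel=1e-8)

    def test_reml_differs_but_betas_agree(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        ml = pg.fit_pgls(data, default_spec, tree, kind="brownian", method="ML")
        reml = pg.fit_pgls(data, default_spec, tree, kind="brownian", method="REML")
        np.testing.assert_allclose(reml.beta, ml.beta, atol=1e-10)
        assert reml.loglik != pytest.approx(ml.loglik, abs=1e-6)


class TestStandardizedBetas:
    def test_equal_sds_give_raw_beta(self, rng):
        tree = random_tree(rng, 20)
        x = rng.normal(size=20)
        data = pd.DataFrame({"x": x, "y": x + rng.normal(size=20) * 1e-3}, index=tree.tips)
        data["y"] = data["y"] * (data["x"].std() / data["y"].std())
        fit = pg.fit_pgls(data, pg.ModelSpec("y", ("x",)), tree, kind="brownian")
        sb = pg.standardized_betas(fit, data)
        assert sb["x"] == pytest.approx(fit.beta["x"], rel=1e-10)

    def test_unit_change_invariance(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        fit1 = pg.fit_pgls(data, default_spec, tree, kind="brownian")
        doubled = data.copy()
        doubled["daily_traveled_distance"] *= 2.0
        fit2 = pg.fit_pgls(doubled, default_spec, tree, kind="brownian")
        assert fit2.beta["daily_traveled_distance"] == pytest.approx(
            fit1.beta["daily_traveled_distance"] / 2.0, rel=1e-8
        )
        assert pg.standardized_betas(fit2, doubled)["daily_traveled_distance"] == pytest.approx(
            pg.standardized_betas(fit1, data)["daily_traveled_distance"], rel=1e-8
        )

    def test_intercept_has_no_standardized_beta(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        fit = pg.fit_pgls(data, default_spec, tree, kind="brownian")
        assert np.isnan(fit.std_beta["(Intercept)"])


class TestLikelihoodRatio:
    def test_identical_fits_give_zero(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        fit = pg.fit_pgls(data, default_spec, tree, kind="brownian")
        stat, df, p = pg.likelihood_ratio_test(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_statistic_is_twice_loglik_gap(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        full = pg.fit_pgls(data, default_spec, tree, kind="brownian")
        reduced = pg.fit_pgls(
            data, pg.ModelSpec("y", ("log10_body_mass",)), tree, kind="brownian"
        )
        stat, df, _ = pg.likelihood_ratio_test(full, reduced)
        assert stat == pytest.approx(max(0.0, 2 * (full.loglik - reduced.loglik)), abs=1e-12)
        assert df == 2

    def test_non_nested_rejected(self, sixteen_tip_dataset):
        _, tree, data = sixteen_tip_dataset
        a = pg.fit_pgls(data, pg.ModelSpec("y", ("log10_body_mass",)), tree)
        b = pg.fit_pgls(data, pg.ModelSpec("y", ("daily_traveled_distance",)), tree)
        with pytest.raises(PGLSError, match="nested"):
            pg.likelihood_ratio_test(a, b)


class TestCoefficientTable:
    def test_layout(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        fit = pg.fit_pgls(data, default_spec, tree, kind="brownian")
        tab = pg.coefficient_table(fit)
        assert list(tab.index)[0] == "(Intercept)"
        assert len(tab) == len(default_spec.terms)
        assert np.isnan(tab.loc["(Intercept)", "Standardized beta"])

    def test_display_rounding_prints_zero_for_tiny_p(self, sixteen_tip_dataset, default_spec):
        _, tree, data = sixteen_tip_dataset
        fit = pg.fit_pgls(data, default_spec, tree, kind="brownian")
        tab = pg.coefficient_table(fit, display_precision=3)
        # intercept p is far below 5e-4 in the default scenario
        assert tab.loc["(Intercept)", "p-Value"] == 0.0
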