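"""Penalized-spline engine: basis/penalty algebra, family fits, GCV
limits, shrinkage behaviour, and AICc."""

import math

import numpy as np
import pandas as pd
import pytest

import sealphen as sp
from sealphen.basis import CubicSplineBasis, cubic_spline_basis
from sealphen.errors import ModelError, InsufficientDataError
from sealphen.gam import (PenalizedGAM, SmoothTerm, RandomIntercept,
                          GamSpec, _center_constraint, aicc, fit_gam)


class TestBasis:
    def test_penalty_annihilates_linear_functions(self):
        x = np.linspace(0, 10, 40)
        B, S = cubic_spline_basis(x, k=10)
        # coefficients of the least-squares representation of a line
        coef, *_ = np.linalg.lstsq(B, 1.5 * x - 2.0, rcond=None)
        assert abs(coef @ S @ coef) < 1e-8
        # and the representation is exact (lines are in the span)
        assert np.allclose(B @ coef, 1.5 * x - 2.0, atol=1e-9)

    def test_penalty_is_psd_with_2d_null_space(self):
        x = np.linspace(0, 1, 30)
        _B, S = cubic_spline_basis(x, k=8)
        eig = np.linalg.eigvalsh(S)
        assert eig.min() > -1e-10
        assert (eig < 1e-8 * eig.max()).sum() == 2

    def test_shrinkage_penalty_has_empty_null_space(self):
        x = np.linspace(0, 1, 30)
        _B, S = cubic_spline_basis(x, k=8, shrinkage=True)
        assert np.linalg.eigvalsh(S).min() > 0

    def test_reproduces_cubic_interpolation(self):
        """A single cubic is in the span: LSQ fit reproduces it exactly."""
        x = np.linspace(-1, 2, 50)
        f = 2 * x ** 3 - x ** 2 + 0.5 * x - 3
        basis = CubicSplineBasis(x, k=10)
        B = basis.evaluate(x)
        coef, *_ = np.linalg.lstsq(B, f, rcond=None)
        knots = np.unique(basis.knots)
        assert np.allclose(
            basis.evaluate(knots) @ coef,
            2 * knots ** 3 - knots ** 2 + 0.5 * knots - 3, atol=1e-8)

    def test_k_reduced_with_warning_and_floor(self, caplog):
        x = np.repeat(np.arange(6.0), 5)
        with caplog.at_level("WARNING"):
            B, _S = cubic_spline_basis(x, k=10)
        assert B.shape[1] == 6
        assert "reduced" in caplog.text
        with pytest.raises(ModelError):
            cubic_spline_basis(np.array([0.0, 1.0, 2.0] * 10), k=10)


class TestGaussianFits:
    def test_linear_truth_reproduced_with_null_space_edf(self):
        x = np.linspace(0, 1, 50)
        data = pd.DataFrame({"x": x, "y": 3 * x + 1})
        fit = fit_gam(GamSpec("y", "gaussian_identity",
                              (SmoothTerm("x", shrinkage=False),)), data)
        assert np.abs(fit.fitted_ - data["y"]).max() < 1e-8
        # edf collapses to the penalty null space (up to the finite
        # selected lambda)
        assert fit.edf_["s(x)"] + fit.edf_["intercept"] <= 2 + 1e-4

    def test_lambda_limits_bracket_null_space_and_unpenalized_fits(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 60)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.2, 60)
        data = pd.DataFrame({"x": x, "y": y})
        term = (SmoothTerm("x", k=8, shrinkage=False),)

        big = PenalizedGAM("y", terms=term, select_lambda=False,
                           fixed_log10_lambda={"s(x)": 12.0}).fit(data)
        coef = np.polyfit(x, y, 1)  # null space = straight line
        assert np.allclose(big.fitted_, np.polyval(coef, x), atol=1e-3)

        small = PenalizedGAM("y", terms=term, select_lambda=False,
                             fixed_log10_lambda={"s(x)": -8.0}).fit(data)
        B, S = cubic_spline_basis(x, k=8)
        Xc, _Sc, _Z = _center_constraint(B, S)
        X = np.hstack([np.ones((60, 1)), Xc])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(small.fitted_, X @ beta, atol=1e-5)

    def test_fixed_lambda_matches_ridge_closed_form(self):
        """Oracle equivalence with penalized least squares."""
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 40)
        y = np.cos(3 * x) + rng.normal(0, 0.1, 40)
        data = pd.DataFrame({"x": x, "y": y})
        fit = PenalizedGAM("y", terms=(SmoothTerm("x", k=8, shrinkage=False),),
                           select_lambda=False,
                           fixed_log10_lambda={"s(x)": 1.0}).fit(data)
        B, S = cubic_spline_basis(x, k=8)
        Xc, Sc, _Z = _center_constraint(B, S)
        Sc = Sc * (np.trace(Xc.T @ Xc) / np.trace(Sc))  # engine scaling
        X = np.hstack([np.ones((40, 1)), Xc])
        P = X.T @ X
        P[1:, 1:] += 10.0 * Sc
        beta = np.linalg.solve(P, X.T @ y)
        assert np.allclose(fit.fitted_, X @ beta, atol=1e-6)


class TestGammaLog:
    def test_matches_glm_oracle_on_known_form(self):
        """statsmodels gamma/log GLM with the true functional form as
        the independent oracle; the smooth must track it closely."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 200)
        y = rng.gamma(50.0, np.exp(0.1 * x) / 50.0)
        data = pd.DataFrame({"x": x, "y": y})
        fit = fit_gam(GamSpec("y", "gamma_log", (SmoothTerm("x"),)), data)
        glm = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Gamma(sm.families.links.Log())).fit()
        eta_gam = np.log(fit.predict(data))
        eta_glm = glm.params[0] + glm.params[1] * x
        assert np.abs(eta_gam - eta_glm).mean() < 0.05

    def test_nonpositive_response_rejected(self):
        data = pd.DataFrame({"x": np.arange(20.0),
                             "y": np.r_[np.ones(19), 0.0]})
        with pytest.raises(ModelError):
            fit_gam(GamSpec("y", "gamma_log", (SmoothTerm("x"),)), data)


class TestShrinkage:
    def test_pure_noise_term_shrinks_to_zero(self):
        """Median edf of a noise covariate under shrinkage < 0.5."""
        edfs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame({"x": rng.uniform(0, 1, 200),
                                 "y": rng.normal(5, 1, 200)})
            fit = fit_gam(GamSpec("y", "gaussian_identity",
                                  (SmoothTerm("x"),)), data)
            edfs.append(fit.edf_["s(x)"])
        assert np.median(edfs) < 0.5


class TestRandomIntercept:
    def test_recovers_group_means_under_light_penalty(self):
        rng = np.random.default_rng(4)
        groups = np.repeat([f"g{i}" for i in range(10)], 20)
        effects = rng.normal(0, 3, 10)
        y = 10 + effects[np.repeat(np.arange(10), 20)] + rng.normal(
            0, 0.5, 200)
        data = pd.DataFrame({"g": groups, "y": y})
        fit = fit_gam(GamSpec("y", "gaussian_identity",
                              (RandomIntercept("g"),)), data)
        pred = fit.predict(data)
        group_means = pd.Series(y).groupby(pd.Series(groups)).mean()
        pred_means = pd.Series(pred).groupby(pd.Series(groups)).mean()
        assert np.abs(group_means - pred_means).max() < 0.3

    def test_unseen_level_predicts_population_mean(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame({"g": np.repeat(["a", "b"], 10),
                             "y": rng.normal(7, 1, 20)})
        fit = fit_gam(GamSpec("y", "gaussian_identity",
                              (RandomIntercept("g"),)), data)
        pred = fit.predict(pd.DataFrame({"g": ["zzz"]}))
        assert pred[0] == pytest.approx(fit.coef_[0])


class TestAicc:
    def test_plugin_arithmetic(self):
        assert aicc(-50.0, 2.0, 100) == pytest.approx(104.1237, abs=1e-3)

    def test_converges_to_aic_for_large_n(self):
        k, ll = 3.0, -10.0
        aic = -2 * ll + 2 * k
        assert abs(aicc(ll, k, 10 ** 6) - aic) < 0.01

    def test_monotone_decreasing_in_loglik(self):
        vals = [aicc(ll, 3.0, 50) for ll in (-30.0, -20.0, -10.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_undefined_when_n_too_small(self):
        with pytest.warns(UserWarning):
            assert aicc(-5.0, 10.0, 11) == math.inf

    def test_hand_computed_linear_model_value(self):
        """Closed-form Gaussian log-likelihood oracle on 20 points."""
        rng = np.random.default_rng(6)
        x = np.linspace(0, 1, 20)
        y = 2 * x + rng.normal(0, 0.3, 20)
        # straight-line fit by hand
        X = np.c_[np.ones(20), x]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        ll = -0.5 * 20 * (math.log(2 * math.pi * rss / 20) + 1)
        k = 3.0  # slope + intercept + scale
        expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (20 - k - 1)
        assert aicc(ll, k, 20) == pytest.approx(expected, rel=1e-12)

    def test_small_n_enforced(self):
        data = pd.DataFrame({"x": np.arange(5.0), "y": np.arange(5.0)})
        with pytest.raises(InsufficientDataError):
            fit_gam(GamSpec("y", "gaussian_identity",
                            (SmoothTerm("x"),)), data)
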