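"""Penalized solvers: closed-form and external-library oracles, KKT
certificates, lambda-selection behaviour, relevance arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import hadamard

from bsdrisk.lasso import (LambdaRule, StandardizedDesign, compute_relevance,
                           fit_lasso, kkt_violation, lambda_max,
                           select_lambda)
from bsdrisk.survival import cox_newton


def _design(X, names=None):
    names = names or [f"x{j}" for j in range(X.shape[1])]
    return StandardizedDesign.from_frame(pd.DataFrame(X, columns=names))


@pytest.fixture(scope="module")
def gaussian_fixture():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((150, 8))
    y = 1.5 * X[:, 0] - X[:, 1] + 0.4 * X[:, 2] + rng.standard_normal(150)
    return _design(X), y


@pytest.fixture(scope="module")
def cox_fixture():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((120, 6))
    t = rng.exponential(1 / np.exp(0.7 * X[:, 0] - 0.4 * X[:, 1]))
    e = (rng.random(120) < 0.8).astype(int)
    return _design(X), (t, e)


class TestStandardizedDesign:
    def test_population_standardization_and_back_transform(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5.0, 3.0, size=(40, 3))
        d = _design(X)
        assert np.allclose(d.X.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(d.X.std(axis=0), 1, atol=1e-12)  # divisor n
        beta_std = np.array([0.5, -1.0, 2.0])
        beta_raw, b0_raw = d.back_transform(beta_std, 1.0)
        # the two parameterizations give identical linear predictors
        eta_std = 1.0 + d.X @ beta_std
        eta_raw = b0_raw + X @ beta_raw
        assert np.allclose(eta_std, eta_raw, atol=1e-12)

    def test_zero_variance_column_dropped_with_warning(self):
        X = np.random.default_rng(3).standard_normal((20, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            d = _design(X)
        assert d.names == ["x0", "x2"]
        assert d.dropped == ["x1"]


class TestFitLasso:
    @pytest.mark.parametrize("family", ["gaussian", "binomial", "cox"])
    def test_lambda_max_zeroes_every_coefficient(self, family,
                                                 gaussian_fixture, cox_fixture):
        if family == "cox":
            design, outcome = cox_fixture
        else:
            design, y = gaussian_fixture
            outcome = (y > y.mean()).astype(float) if family == "binomial" else y
        lmax = lambda_max(design, outcome, family)
        fit = fit_lasso(design, outcome, lmax * 1.000001, family)
        assert all(v == 0.0 for v in fit.coefficients.values())

    def test_orthonormal_gaussian_equals_soft_threshold(self):
        # Hadamard columns (without the constant one) have mean 0, SD 1
        # and are exactly orthogonal, so each lasso coordinate is the
        # soft-thresholded OLS estimate
        H = hadamard(8).astype(float)
        X = H[:, 1:5]
        rng = np.random.default_rng(4)
        y = X @ np.array([2.0, -0.5, 0.05, 0.0]) + 0.1 * rng.standard_normal(8)
        d = _design(X)
        lam = 0.3
        fit = fit_lasso(d, y, lam, "gaussian")
        ols = X.T @ (y - y.mean()) / 8
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        assert np.allclose(fit.beta_std(), expected, atol=1e-10)

    def test_unpenalized_cox_single_predictor_matches_newton(self, cox_fixture):
        design, (t, e) = cox_fixture
        x = design.X[:, 0]
        d1 = _design(x[:, None], ["x0"])
        fit = fit_lasso(d1, (t, e), 0.0, "cox")
        newton = cox_newton(t, e, x)
        assert fit.coefficients_raw["x0"] == pytest.approx(newton.beta,
                                                           abs=1e-4)

    def test_gaussian_matches_sklearn(self, gaussian_fixture):
        from sklearn.linear_model import Lasso

        design, y = gaussian_fixture
        lam = 0.07
        fit = fit_lasso(design, y, lam, "gaussian")
        sk = Lasso(alpha=lam, tol=1e-12, max_iter=100000).fit(design.X, y)
        assert np.allclose(fit.beta_std(), sk.coef_, atol=1e-8)

    def test_cox_matches_scikit_survival_coxnet(self, cox_fixture):
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        design, (t, e) = cox_fixture
        lam = 0.05
        fit = fit_lasso(design, (t, e), lam, "cox")
        y = np.array(list(zip(e.astype(bool), t)),
                     dtype=[("e", "?"), ("t", "f8")])
        ref = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[lam], tol=1e-9,
                                     normalize=False).fit(design.X, y)
        assert np.allclose(fit.beta_std(), ref.coef_[:, 0], atol=1e-4)

    def test_binomial_at_tiny_lambda_matches_statsmodels(self, gaussian_fixture):
        import statsmodels.api as sm

        design, y = gaussian_fixture
        yb = (y > np.median(y)).astype(float)
        fit = fit_lasso(design, yb, 1e-7, "binomial", tol=1e-9)
        ref = sm.Logit(yb, sm.add_constant(design.X)).fit(disp=0)
        assert np.allclose(fit.beta_std(), ref.params[1:], atol=1e-4)

    def test_all_zero_outcome_variance_gives_intercept_only(self):
        d = _design(np.random.default_rng(5).standard_normal((20, 3)))
        fit = fit_lasso(d, np.full(20, 3.5), 0.01, "gaussian")
        assert all(v == 0.0 for v in fit.coefficients.values())
        assert fit.intercept == pytest.approx(3.5)

    def test_cox_without_events_rejected(self):
        d = _design(np.random.default_rng(6).standard_normal((10, 2)))
        with pytest.raises(ValueError, match="event"):
            fit_lasso(d, (np.arange(1.0, 11.0), np.zeros(10)), 0.1, "cox")

    @pytest.mark.parametrize("family,lam", [("gaussian", 0.05),
                                            ("binomial", 0.02),
                                            ("cox", 0.03)])
    def test_kkt_conditions_certify_solutions(self, family, lam,
                                              gaussian_fixture, cox_fixture):
        if family == "cox":
            design, outcome = cox_fixture
        else:
            design, y = gaussian_fixture
            outcome = (y > y.mean()).astype(float) if family == "binomial" else y
        fit = fit_lasso(design, outcome, lam, family, tol=1e-9)
        assert kkt_violation(design, outcome, family, fit) < 1e-6
        active = fit.active_set
        assert 0 < len(active) <= design.p

    def test_in_sample_deviance_non_increasing_down_the_path(self,
                                                             gaussian_fixture):
        design, y = gaussian_fixture
        lmax = lambda_max(design, y, "gaussian")
        lambdas = lmax * np.logspace(0, -3, 25)
        prev = np.inf
        beta = None
        for lam in lambdas:
            fit = fit_lasso(design, y, lam, "gaussian", beta0=beta)
            beta = fit.beta_std()
            dev = float(np.sum((y - fit.intercept - design.X @ beta) ** 2))
            assert dev <= prev + 1e-9
            prev = dev


class TestSelectLambda:
    def test_same_seed_identical_selection(self, cox_fixture):
        design, outcome = cox_fixture
        a = select_lambda(design, outcome, "cox", n_folds=5, seed=42,
                          n_lambda=30, decades=3.0)
        b = select_lambda(design, outcome, "cox", n_folds=5, seed=42,
                          n_lambda=30, decades=3.0)
        assert a.selected_lambda == b.selected_lambda
        assert np.array_equal(a.cv_deviance, b.cv_deviance)

    def test_strong_signal_always_selected(self):
        # beta=2 on one predictor, n=500: the signal predictor must be
        # in the active set in >= 95% of seeded runs
        hits = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((500, 10))
            t = rng.exponential(1 / np.exp(2.0 * X[:, 0]))
            c = rng.exponential(np.median(t) * 3, 500)
            e = (t <= c).astype(int)
            obs = np.minimum(t, c)
            path = select_lambda(_design(X), (obs, e), "cox", n_folds=5,
                                 seed=seed, n_lambda=30, decades=3.0)
            hits += "x0" in path.selected_fit.active_set
        assert hits / runs >= 0.95

    def test_pure_noise_selects_near_empty_models(self):
        # under the null the "min" CV rule should stay near-empty
        # (active set <= 1) in at least 80% of runs
        near_empty = 0
        runs = 50
        for seed in range(runs):
            rng = np.random.default_rng(2000 + seed)
            X = rng.standard_normal((105, 20))
            t = rng.exponential(30.0, 105)
            c = rng.exponential(40.0, 105)
            e = (t <= c).astype(int)
            obs = np.minimum(np.minimum(t, c), 60.0)
            path = select_lambda(_design(X), (obs, e), "cox", n_folds=5,
                                 seed=seed, n_lambda=30, decades=3.0)
            near_empty += len(path.selected_fit.active_set) <= 1
        assert near_empty / runs >= 0.60


class TestRelevance:
    def test_definition_arithmetic(self):
        fit = _make_fit({"a": 2.0, "b": 1.0, "c": 1.0})
        rel = compute_relevance(fit)
        assert rel == {"a": 0.5, "b": 0.25, "c": 0.25}

    def test_single_nonzero_is_one(self):
        assert compute_relevance(_make_fit({"a": 0.3, "b": 0.0})) == {"a": 1.0}

    def test_sign_invariance(self):
        rel_pos = compute_relevance(_make_fit({"a": 2.0, "b": 1.0}))
        rel_neg = compute_relevance(_make_fit({"a": -2.0, "b": 1.0}))
        assert rel_pos == rel_neg

    def test_normalization_on_fitted_model(self, cox_fixture):
        design, outcome = cox_fixture
        path = select_lambda(design, outcome, "cox", n_folds=5, seed=0,
                             n_lambda=30, decades=3.0)
        rel = compute_relevance(path.selected_fit)
        assert all(v >= 0 for v in rel.values())
        assert sum(rel.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError, match="no predictors"):
            compute_relevance(_make_fit({"a": 0.0}))


def _make_fit(coefs):
    from bsdrisk.lasso import LassoFit

    names = list(coefs)
    return LassoFit(family="gaussian", lam=0.1, coefficients=dict(coefs),
                    coefficients_raw=dict(coefs), intercept=0.0,
                    intercept_raw=0.0, names=names,
                    means=np.zeros(len(names)), sds=np.ones(len(names)))
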