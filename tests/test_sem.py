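"""Structural model: RAM algebra, FIML likelihood and gradient, estimation
against a moment-based ML oracle, fit indices and standardization."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from conftest import MEDIATION_TRUTH, make_mediation_data, mediation_spec
from latentmed.sem import (
    SEMMatrices,
    SEMModel,
    SEMSpec,
    default_pathway_spec,
    fit_sem,
    implied_moments,
    mvn_missing_ml,
    parse_model_syntax,
    saturated_baseline,
    standardize_solution,
    _em_saturated,
    _pattern_groups,
)


# ---------------------------------------------------------------------------
# specification


class TestSpec:
    def test_parser_roundtrip(self):
        spec = parse_model_syntax(
            """
            M =~ m1 + m2 + m3   # mediator factor
            Y =~ y1 + y2 + y3
            M ~ x
            Y ~ M + x
            """
        )
        ref = mediation_spec()
        assert spec.latents == ref.latents
        assert spec.regressions == ref.regressions

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            SEMSpec(regressions={"a": ["b"], "b": ["a"]})

    def test_latent_cannot_be_indicator(self):
        with pytest.raises(ValueError, match="both"):
            SEMSpec(latents={"F": ["x1", "G"], "G": ["x2"]})

    def test_default_pathway_shape(self):
        spec = default_pathway_spec()
        assert set(spec.latents) == {"SVD", "ADpath", "Neuro", "Cognition"}
        assert len(spec.observed) == 19
        assert spec.exogenous == ["si_score", "li_score", "age", "sex", "apoe4"]


# ---------------------------------------------------------------------------
# implied moments


def _matrices(A, S, m, obs_idx, names):
    return SEMMatrices(
        A=np.asarray(A, float),
        S=np.asarray(S, float),
        m=np.asarray(m, float),
        obs_idx=np.asarray(obs_idx),
        variables=names,
    )


class TestImpliedMoments:
    def test_no_paths_reduces_to_s_and_m(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        m = np.array([1.0, -1.0])
        mu, sig = implied_moments(
            _matrices(np.zeros((2, 2)), S, m, [0, 1], ["a", "b"])
        )
        np.testing.assert_allclose(sig, S)
        np.testing.assert_allclose(mu, m)

    def test_single_indicator_latent_reduces_to_path_analysis(self):
        # y = 0.7 x + e: via a latent with loading 1 and zero residual the
        # implied covariance equals the regression-implied one
        names = ["y", "x", "F"]
        A = np.zeros((3, 3))
        A[0, 2] = 1.0          # y <- F (loading 1)
        A[2, 1] = 0.7          # F <- x
        S = np.diag([0.0, 2.0, 0.5])  # zero indicator residual
        mu, sig = implied_moments(_matrices(A, S, np.zeros(3), [0, 1], names))
        var_y = 0.7**2 * 2.0 + 0.5
        np.testing.assert_allclose(
            sig, [[var_y, 0.7 * 2.0], [0.7 * 2.0, 2.0]], atol=1e-12
        )

    def test_matches_generative_recursion_simulation(self):
        # independent oracle: simulate the recursion directly and compare
        rng = np.random.default_rng(12)
        n = 200_000
        a, b, lam = 0.6, -0.4, 1.3
        x = rng.standard_normal(n) * 1.5
        F = a * x + rng.standard_normal(n) * 0.9
        y1 = F + 0.5 * rng.standard_normal(n)
        y2 = lam * F + 0.7 * rng.standard_normal(n)
        z = b * x + 0.8 * rng.standard_normal(n)
        draws = np.column_stack([y1, y2, z, x])

        names = ["y1", "y2", "z", "x", "F"]
        A = np.zeros((5, 5))
        A[0, 4] = 1.0
        A[1, 4] = lam
        A[2, 3] = b
        A[4, 3] = a
        S = np.diag([0.25, 0.49, 0.64, 2.25, 0.81])
        mu, sig = implied_moments(
            _matrices(A, S, np.zeros(5), [0, 1, 2, 3], names)
        )
        emp = np.cov(draws.T, ddof=0)
        d = np.diag(sig)
        se = np.sqrt((np.outer(d, d) + sig**2) / n)
        assert np.all(np.abs(emp - sig) < 4.0 * se)

    def test_singular_system_reports_cycle(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="cyclic|singular"):
            implied_moments(
                _matrices(A, np.eye(2), np.zeros(2), [0, 1], ["a", "b"])
            )


# ---------------------------------------------------------------------------
# FIML likelihood kernel


class TestFIMLLoglik:
    def test_single_observation_closed_form(self):
        patterns = _pattern_groups(np.array([[0.0]]))
        ll = mvn_missing_ml(np.zeros(1), np.eye(1), patterns)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_complete_data_equals_mvn_logpdf(self):
        rng = np.random.default_rng(0)
        mu = np.array([1.0, -0.5, 0.2])
        sig = np.array([[2.0, 0.3, 0.1], [0.3, 1.0, -0.2], [0.1, -0.2, 1.5]])
        X = rng.multivariate_normal(mu, sig, 50)
        ll = mvn_missing_ml(mu, sig, _pattern_groups(X))
        ref = multivariate_normal(mu, sig).logpdf(X).sum()
        assert ll == pytest.approx(ref, rel=1e-12)

    def test_additive_over_data_splits(self):
        X = make_mediation_data(120, 5, mcar=0.2).to_numpy()
        X = X[~np.all(np.isnan(X), axis=1)]
        mu = np.zeros(X.shape[1])
        sig = np.eye(X.shape[1]) + 0.1
        ll_all = mvn_missing_ml(mu, sig, _pattern_groups(X))
        ll_a = mvn_missing_ml(mu, sig, _pattern_groups(X[:60]))
        ll_b = mvn_missing_ml(mu, sig, _pattern_groups(X[60:]))
        assert ll_all == pytest.approx(ll_a + ll_b, rel=1e-12)

    def test_analytic_gradient_matches_finite_differences(self):
        data = make_mediation_data(150, 42, mcar=0.25)
        model = SEMModel(mediation_spec(), data)
        rng = np.random.default_rng(3)
        theta = model.start_values()
        theta += 0.05 * rng.standard_normal(theta.size) * np.maximum(
            np.abs(theta), 0.1
        )
        ll, grad = model.loglik_grad(theta)
        for k in rng.choice(model.n_free, 15, replace=False):
            h = 1e-6 * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            num = (model.loglik(tp) - model.loglik(tm)) / (2 * h)
            assert grad[k] == pytest.approx(num, rel=1e-5, abs=1e-4)


# ---------------------------------------------------------------------------
# estimation


class TestFitSEM:
    def test_complete_data_matches_covariance_ml_oracle(self, mediation_fit):
        # oracle: minimize the moment-based ML discrepancy
        # log|Sigma| + tr(S Sigma^-1) + (xbar-mu)' Sigma^-1 (xbar-mu)
        # on the sample moments -- an independent computational route
        fit = mediation_fit
        model = fit.model
        X = model.X
        n = X.shape[0]
        S = np.cov(X.T, ddof=0)
        xbar = X.mean(axis=0)
        d = model.param_scales()

        def discrepancy(u):
            mat = model.matrices(d * u)
            mu, sig = implied_moments(mat)
            try:
                L = np.linalg.cholesky(sig)
            except np.linalg.LinAlgError:
                return 1e10
            isig = np.linalg.inv(sig)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            diff = xbar - mu
            return logdet + np.trace(S @ isig) + diff @ isig @ diff

        res = minimize(
            discrepancy,
            fit.theta / d,
            method="Nelder-Mead",
            options={"maxiter": 60000, "xatol": 1e-9, "fatol": 1e-12},
        )
        res = minimize(
            discrepancy, res.x, method="Nelder-Mead",
            options={"maxiter": 60000, "xatol": 1e-10, "fatol": 1e-13},
        )
        oracle = d * res.x
        np.testing.assert_allclose(fit.theta, oracle, atol=1e-4)

    def test_saturated_spec_zero_chi_square(self):
        # just-identified path system: y ~ x + z with x ~~ z frees exactly
        # as many parameters as there are observed moments
        rng = np.random.default_rng(9)
        n = 500
        x = rng.standard_normal(n)
        z = 0.5 * x + rng.standard_normal(n)
        y = 0.3 * x - 0.2 * z + rng.standard_normal(n)
        data = pd.DataFrame({"y": y, "x": x, "z": z})
        spec = SEMSpec(regressions={"y": ["x", "z"]}, covariances=[("x", "z")])
        fit = fit_sem(spec, data)
        assert fit.df_model == 0
        assert abs(fit.chi_square) < 1e-4

    def test_scale_equivariance(self, mediation_data):
        spec = mediation_spec()
        fit1 = fit_sem(spec, mediation_data, compute_indices=True)
        scaled = mediation_data.copy()
        c = 10.0
        scaled["m2"] = scaled["m2"] * c
        fit2 = fit_sem(spec, scaled, compute_indices=True)
        # loading and residual variance rescale accordingly
        k_load = fit1.lookup("M", "=~", "m2")
        k_var = fit1.lookup("m2", "~~", "m2")
        assert fit2.theta[k_load] == pytest.approx(c * fit1.theta[k_load], rel=1e-4)
        assert fit2.theta[k_var] == pytest.approx(
            c**2 * fit1.theta[k_var], rel=1e-4
        )
        # fit indices unchanged
        for key in ("chi_square", "rmsea", "cfi", "tli", "srmr"):
            assert fit2.indices[key] == pytest.approx(
                fit1.indices[key], abs=1e-4
            )
        # standardized solution unchanged
        standardize_solution(fit1)
        standardize_solution(fit2)
        np.testing.assert_allclose(fit1.std_theta, fit2.std_theta, atol=1e-5)

    def test_mcar_fiml_less_variable_than_listwise(self):
        # under 30% MCAR, FIML uses partial rows; listwise deletion drops
        # them and pays in sampling variance
        a_fiml, a_lw = [], []
        spec = mediation_spec()
        for seed in range(20):
            data = make_mediation_data(600, 1000 + seed, mcar=0.3)
            f1 = fit_sem(spec, data, compute_indices=False, compute_se=False)
            complete = data.dropna()
            f2 = fit_sem(spec, complete, compute_indices=False, compute_se=False)
            k = f1.lookup("M", "~", "x")
            a_fiml.append(f1.theta[k])
            a_lw.append(f2.theta[f2.lookup("M", "~", "x")])
        a_fiml, a_lw = np.asarray(a_fiml), np.asarray(a_lw)
        # unbiasedness within MC error
        mc_se = a_fiml.std(ddof=1) / np.sqrt(len(a_fiml))
        assert abs(a_fiml.mean() - MEDIATION_TRUTH["a"]) < 3 * mc_se + 0.01
        assert a_lw.var(ddof=1) > a_fiml.var(ddof=1)


# ---------------------------------------------------------------------------
# saturated / baseline models and indices


class TestSaturatedBaseline:
    def test_complete_data_closed_form(self):
        X = make_mediation_data(300, 77).to_numpy()
        mu, sig, ll = _em_saturated(X)
        np.testing.assert_allclose(mu, X.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(sig, np.cov(X.T, ddof=0), atol=1e-8)

    def test_baseline_nested_in_saturated(self):
        data = make_mediation_data(250, 8, mcar=0.2)
        ll_sat, ll_base, _, df_base = saturated_baseline(data)
        assert ll_base <= ll_sat
        p = data.shape[1]
        assert df_base == p * (p - 1) // 2

    def test_model_df_counting(self, mediation_fit):
        p = len(mediation_fit.model.spec.observed)
        n_moments = p * (p + 3) // 2
        assert mediation_fit.df_model == n_moments - mediation_fit.model.n_free


class TestFitIndices:
    def test_rmsea_zero_when_chi_square_at_df(self, mediation_fit):
        from latentmed.sem import fit_indices

        probe = mediation_fit
        saved = (probe.ll_saturated, probe.ll_baseline)
        try:
            probe.ll_saturated = probe.loglik + probe.df_model / 2.0  # T = df
            idx = fit_indices(probe, probe.n_obs)
            assert idx["rmsea"] == 0.0
            # misfitting model no better than baseline -> CFI 0
            probe.ll_saturated = probe.loglik + probe.df_model  # T = 2 df
            probe.ll_baseline = probe.loglik
            idx = fit_indices(probe, probe.n_obs)
            assert idx["cfi"] == pytest.approx(0.0, abs=1e-12)
        finally:
            probe.ll_saturated, probe.ll_baseline = saved

    def test_correctly_specified_model_fits_well(self, mediation_fit):
        assert mediation_fit.indices["rmsea"] < 0.03
        assert mediation_fit.indices["cfi"] > 0.99
        assert mediation_fit.indices["srmr"] < 0.05

    def test_chi_square_calibration(self):
        # under the true model T ~ chi-square(df): the empirical mean over
        # replicates must sit within 10% of df
        spec = SEMSpec(latents={"F": ["v1", "v2", "v3"]}, regressions={"F": ["x"]})
        rng = np.random.default_rng(2024)
        Ts, df = [], None
        for _ in range(200):
            n = 300
            x = rng.standard_normal(n)
            F = 0.5 * x + rng.standard_normal(n)
            data = pd.DataFrame(
                {
                    "v1": F + 0.6 * rng.standard_normal(n),
                    "v2": 0.8 * F + 0.6 * rng.standard_normal(n),
                    "v3": 0.7 * F + 0.6 * rng.standard_normal(n),
                    "x": x,
                }
            )
            fit = fit_sem(spec, data, compute_se=False)
            Ts.append(fit.chi_square)
            df = fit.df_model
        mean_T = float(np.mean(Ts))
        assert df > 0
        assert abs(mean_T - df) < 0.10 * df


# ---------------------------------------------------------------------------
# standardization


class TestStandardize:
    def test_idempotent_on_standardized_system(self):
        # all variables near unit variance: standardized ~ raw
        data = make_mediation_data(
            4000,
            31,
            truth={
                "loadings_m": (1.0, 1.0, 1.0),
                "loadings_y": (1.0, 1.0, 1.0),
                "resid_ind": 1e-4,
            },
        )
        fit = fit_sem(mediation_spec(), data, compute_indices=False)
        standardize_solution(fit)
        for lhs, op, rhs in [("M", "~", "x"), ("Y", "~", "M"), ("Y", "~", "x")]:
            k = fit.lookup(lhs, op, rhs)
            # var(M), var(Y) close to but not exactly 1; loose tolerance
            assert fit.std_theta[k] == pytest.approx(fit.theta[k], abs=0.05)

    def test_exogenous_variance_standardizes_to_one(self, mediation_fit):
        k = mediation_fit.lookup("x", "~~", "x")
        assert mediation_fit.std_theta[k] == pytest.approx(1.0, abs=1e-10)

    def test_delta_ses_positive_for_structural_paths(self, mediation_fit):
        for lhs, op, rhs in [("M", "~", "x"), ("Y", "~", "M"), ("Y", "~", "x")]:
            k = mediation_fit.lookup(lhs, op, rhs)
            assert mediation_fit.std_cov[k, k] > 0
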