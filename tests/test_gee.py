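"""GEE engine: oracle equivalences, invariances, convergence semantics."""

import numpy as np
import pytest
import statsmodels.api as sm

import rdgee
from rdgee import FitControl, ModelSpec, fit_gee
from rdgee.exceptions import ConfigError, DataError, NotConvergedError


def _sm_family(name, link):
    links = {"identity": sm.families.links.Identity(),
             "log": sm.families.links.Log(),
             "logit": sm.families.links.Logit()}
    fams = {"binomial": sm.families.Binomial,
            "poisson": sm.families.Poisson,
            "normal": sm.families.Gaussian}
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fams[name](link=links[link])


class TestAgainstStatsmodels:
    """statsmodels GEE is the independent cross-check, never the engine."""

    @pytest.mark.parametrize("family,link", rdgee.GEE_MODELS.values(),
                             ids=list(rdgee.GEE_MODELS))
    def test_exchangeable_fit_matches(self, beitler, family, link):
        import warnings
        fit = fit_gee(beitler, ModelSpec(family, link))
        assert fit.converged
        df = beitler.to_dataframe()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE.from_formula(
                "outcome ~ treatment", groups="center", data=df,
                family=_sm_family(family, link),
                cov_struct=sm.cov_struct.Exchangeable(),
            )
            res = model.fit()
        np.testing.assert_allclose(fit.coefficients, res.params.values,
                                   rtol=1e-5, atol=1e-7)
        assert fit.icc == pytest.approx(model.cov_struct.dep_params, abs=1e-3)

    def test_independence_sandwich_matches(self, beitler):
        import warnings
        fit = fit_gee(beitler, ModelSpec("binomial", "logit"),
                      FitControl(fixed_rho=0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GEE.from_formula(
                "outcome ~ treatment", groups="center",
                data=beitler.to_dataframe(), family=sm.families.Binomial(),
                cov_struct=sm.cov_struct.Independence(),
            ).fit()
        np.testing.assert_allclose(fit.coefficients, res.params.values, rtol=1e-6)
        np.testing.assert_allclose(fit.robust_cov, np.asarray(res.cov_robust),
                                   rtol=1e-6)

    def test_independence_equals_glm_coefficients(self, beitler):
        fit = fit_gee(beitler, ModelSpec("binomial", "logit"),
                      FitControl(fixed_rho=0.0))
        df = beitler.to_dataframe()
        glm = sm.GLM(df["outcome"], sm.add_constant(df["treatment"].astype(float)),
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients, glm.params.values, rtol=1e-8)


def test_normal_identity_rho0_is_least_squares(beitler):
    """With independence working correlation, normal/identity is exactly OLS."""
    fit = fit_gee(beitler, ModelSpec("normal", "identity"),
                  FitControl(fixed_rho=0.0))
    X = np.column_stack([np.ones(beitler.n), beitler.treatment])
    ols = np.linalg.lstsq(X, beitler.outcome.astype(float), rcond=None)[0]
    np.testing.assert_allclose(fit.coefficients, ols, atol=1e-10)


def test_table_models_agree_on_rd(beitler):
    """All six marginal models land essentially on the same RD (published
    values span 0.125-0.127)."""
    rds = []
    for label in rdgee.GEE_MODELS:
        fit = fit_gee(beitler, ModelSpec.from_label(label))
        rds.append(rdgee.estimate_rd(fit).rd)
    assert max(rds) - min(rds) < 0.0025
    assert all(0.1245 < rd < 0.1275 for rd in rds)


def test_coefficients_invariant_to_relabeling_and_order(beitler):
    rng = np.random.default_rng(3)
    perm = rng.permutation(beitler.n)
    relabeled = rdgee.TrialData(
        center=np.array([f"c{c}" for c in beitler.center[perm]]),
        treatment=beitler.treatment[perm],
        outcome=beitler.outcome[perm],
    )
    a = fit_gee(beitler, ModelSpec("binomial", "identity"))
    b = fit_gee(relabeled, ModelSpec("binomial", "identity"))
    np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-9)
    assert a.icc == pytest.approx(b.icc, abs=1e-9)


def test_zero_icc_structure(covariate_trial):
    """Centers with identical outcome patterns: rho-hat near 0, OLS recovered."""
    # replicate one center's records across 6 centers -> no between-center variation
    n = 30
    base_t = np.tile([0, 1], n // 2)
    base_y = np.tile([0, 0, 1, 0, 0, 1], n // 6)
    data = rdgee.TrialData(
        center=np.repeat(np.arange(6), n),
        treatment=np.tile(base_t, 6),
        outcome=np.tile(base_y, 6),
    )
    fit = fit_gee(data, ModelSpec("normal", "identity"))
    assert abs(fit.icc) < 0.05
    X = np.column_stack([np.ones(data.n), data.treatment])
    ols = np.linalg.lstsq(X, data.outcome.astype(float), rcond=None)[0]
    np.testing.assert_allclose(fit.coefficients, ols, atol=1e-6)


class TestPredictProb:
    def test_logistic_at_zero(self, beitler):
        fit = fit_gee(beitler, ModelSpec("binomial", "logit"))
        fit.coefficients = np.zeros_like(fit.coefficients)
        assert fit.predict_prob(1) == pytest.approx(0.5)
        assert fit.predict_prob(0) == pytest.approx(0.5)

    def test_log_inverse(self, beitler):
        fit = fit_gee(beitler, ModelSpec("binomial", "log"))
        fit.coefficients = np.array([np.log(0.25), 0.3])
        assert fit.predict_prob(0) == pytest.approx(0.25)

    def test_identity_fitted_rate(self, beitler):
        fit = fit_gee(beitler, ModelSpec("binomial", "identity"))
        expected = fit.coefficients[0] + fit.coefficients[1]
        assert fit.predict_prob(1) == pytest.approx(expected)

    def test_refuses_nonconverged(self, beitler):
        fit = fit_gee(beitler, ModelSpec("binomial", "identity"),
                      FitControl(max_iter=1, tol=1e-14))
        assert not fit.converged
        with pytest.raises(NotConvergedError):
            fit.predict_prob(1)


class TestConvergenceSemantics:
    def test_iteration_cap_is_not_an_exception(self, beitler):
        fit = fit_gee(beitler, ModelSpec("poisson", "log"),
                      FitControl(max_iter=1, tol=1e-14))
        assert fit.converged is False
        assert "iteration limit" in fit.message

    def test_log_binomial_boundary_failure(self):
        """Outcome rates near 1 push log-link fitted means to >= 1."""
        rng = np.random.default_rng(5)
        n = 40
        data = rdgee.TrialData(
            center=np.repeat(np.arange(4), n),
            treatment=np.tile([0, 1], 2 * n),
            outcome=(rng.random(4 * n) < 0.97).astype(int),
        )
        fit = fit_gee(data, ModelSpec("binomial", "log"))
        # either it converged with all means < 1 or it reported failure — never raised
        if fit.converged:
            assert fit.predict_prob(1) < 1.0
        else:
            assert "inadmissible" in fit.message or "limit" in fit.message

    def test_missing_covariate_is_structural(self, beitler):
        with pytest.raises(DataError):
            fit_gee(beitler, ModelSpec("binomial", "identity", include_covariate=True))

    def test_bad_model_spec_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec("normal", "logit")

    def test_icc_needs_within_center_pairs(self):
        data = rdgee.TrialData(
            center=np.arange(8), treatment=np.tile([0, 1], 4),
            outcome=np.tile([0, 1], 4),
        )
        with pytest.raises(DataError, match="pairs"):
            fit_gee(data, ModelSpec("binomial", "identity"))


def test_covariate_fit_has_three_coefficients(covariate_trial):
    fit = fit_gee(covariate_trial, ModelSpec("binomial", "identity",
                                             include_covariate=True))
    assert fit.converged
    assert fit.coef_names == ("intercept", "treatment", "covariate")
    assert fit.n_params_p == 2
    assert np.all(np.diag(fit.robust_cov) > 0)
    assert np.allclose(fit.robust_cov, fit.robust_cov.T)
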