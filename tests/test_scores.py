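"""Factor scoring, standardization and correlation tables."""

import numpy as np
import pandas as pd
import pytest

import pfactorlab as pf
from pfactorlab.scores import FactorScores
from conftest import toy_single_factor_spec


def _toy_fit(p=4, lam_val=0.7, n=200, seed=0):
    spec = toy_single_factor_spec(p)
    lam = np.full(p, lam_val)
    sigma = np.outer(lam, lam) + np.diag(1 - lam**2)
    fit = pf.fit_ml(pf.SampleMoments.from_covariance(sigma, n), spec)
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(rng.standard_normal((50, p)), columns=spec.indicators)
    return fit, data


class TestRegressionScores:
    def test_single_indicator_limit_equals_standardized_indicator(self):
        spec = toy_single_factor_spec(1)
        params = pf.ParameterSet(
            loadings=np.array([[1.0]]),
            factor_correlations=np.eye(1),
            residual_variances=np.array([1e-10]),
        )
        from pfactorlab.cfa import FitResult

        fit = FitResult(spec=spec, params=params, theta=np.array([1.0, 1e-10]),
                        f_min=0.0, chi2_naive=0.0, df=0, n=100, converged=True,
                        gradient_norm=0.0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        data = pd.DataFrame({"x0": x})
        scores = pf.regression_scores(fit, data, means=np.array([0.0]), sds=np.array([1.0]))
        assert np.allclose(scores.scores["g"], x, atol=1e-6)

    def test_matches_per_subject_gls_oracle(self):
        # posterior/GLS solve per subject: (Phi^-1 + L'Th^-1 L)^-1 L'Th^-1 x
        fit, data = _toy_fit()
        scores = pf.regression_scores(fit, data, means=np.zeros(4), sds=np.ones(4))
        lam = fit.params.loadings
        theta_inv = np.diag(1.0 / fit.params.residual_variances)
        phi_inv = np.linalg.inv(fit.params.factor_correlations)
        m = np.linalg.inv(phi_inv + lam.T @ theta_inv @ lam) @ lam.T @ theta_inv
        for r in range(10):
            x = data.iloc[r].to_numpy()
            assert np.allclose(scores.scores.iloc[r].to_numpy(), m @ x, atol=1e-10)

    def test_total_sample_weights_applied_to_subgroup_members(self, small_population, small_population_fit):
        # scoring a subset with the full-sample fit must equal the row subset
        # of full-sample scores: no refitting, no re-standardization
        full = pf.regression_scores(small_population_fit, small_population.symptoms)
        members = small_population.symptoms.index[:500]
        sub = pf.regression_scores(small_population_fit, small_population.symptoms.loc[members])
        assert np.allclose(sub.scores.to_numpy(), full.scores.loc[members].to_numpy())

    def test_bartlett_scores_unbiased_weights(self):
        fit, data = _toy_fit()
        scores = pf.regression_scores(fit, data, means=np.zeros(4), sds=np.ones(4),
                                      method="bartlett")
        lam = fit.params.loadings
        theta_inv = np.diag(1.0 / fit.params.residual_variances)
        w = theta_inv @ lam @ np.linalg.inv(lam.T @ theta_inv @ lam)
        # Bartlett weights reproduce the factor identity: w' Lambda = I
        assert np.allclose(w.T @ lam, np.eye(1), atol=1e-12)
        assert np.allclose(scores.scores.to_numpy(), data.to_numpy() @ w, atol=1e-12)

    def test_score_recovery_matches_factor_determinacy_on_normal_data(self):
        # on multivariate-normal data the regression score's correlation with
        # the true factor converges to the factor determinacy
        # sqrt(diag(Phi L' Sigma^-1 L Phi))
        pop = pf.generate_population(pf.SimulationConfig(
            n_subjects=20_000, seed=17, target_skew=0.0, target_excess_kurtosis=0.0))
        fit = pf.fit_ml(pf.SampleMoments.from_data(pop.symptoms.to_numpy()),
                        pf.build_model("C_revised_bifactor"))
        lam, phi = fit.params.loadings, fit.params.factor_correlations
        determinacy = np.sqrt(np.diag(phi @ lam.T @ np.linalg.solve(fit.implied, lam @ phi)))
        scores = pf.regression_scores(fit, pop.symptoms)
        for j, f in enumerate(fit.spec.factor_labels):
            r = np.corrcoef(scores.scores[f], pop.latent_scores[f])[0, 1]
            assert r == pytest.approx(determinacy[j], abs=0.03), f

    def test_general_factor_recovery_on_skewed_data(self, small_population, small_population_fit):
        # the marginal skew transform attenuates latent-indicator correlations,
        # but the strongly determined general factor still recovers above .9
        scores = pf.regression_scores(small_population_fit, small_population.symptoms)
        assert np.corrcoef(scores.scores["p"], small_population.latent_scores["p"])[0, 1] > 0.9


class TestStandardization:
    def _scores(self, seed=4):
        rng = np.random.default_rng(seed)
        return FactorScores(scores=pd.DataFrame({"p": rng.normal(3, 2, 1_000)}))

    def test_exact_mean_and_sd(self):
        out = pf.standardize_scores(self._scores())
        assert out.scores["p"].mean() == pytest.approx(100.0, abs=1e-9)
        assert out.scores["p"].std(ddof=0) == pytest.approx(15.0, abs=1e-9)

    def test_idempotent(self):
        once = pf.standardize_scores(self._scores())
        twice = pf.standardize_scores(once)
        assert np.allclose(once.scores["p"], twice.scores["p"], atol=1e-9)

    def test_correlations_invariant(self):
        scores = self._scores()
        rng = np.random.default_rng(5)
        cov = pd.DataFrame({"VC": scores.scores["p"] * 0.3 + rng.normal(0, 1, 1_000)})
        before = pf.covariate_correlations(scores, cov)
        after = pf.covariate_correlations(pf.standardize_scores(scores), cov)
        assert before.loc["p", "VC_r"] == pytest.approx(after.loc["p", "VC_r"], abs=1e-12)

    def test_constant_scores_rejected(self):
        scores = FactorScores(scores=pd.DataFrame({"p": np.ones(10)}))
        with pytest.raises(ValueError, match="constant"):
            pf.standardize_scores(scores)


class TestCorrelationTables:
    def test_identical_scores_correlate_perfectly(self):
        rng = np.random.default_rng(6)
        s = FactorScores(scores=pd.DataFrame({"Ext": rng.normal(size=500)}))
        table = pf.cross_derivation_correlations(s, s)
        assert table.loc["Ext", "Ext_r"] == pytest.approx(1.0)

    def test_anticorrelated_columns(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=500)
        a = FactorScores(scores=pd.DataFrame({"p": x}))
        b = FactorScores(scores=pd.DataFrame({"p": -x}))
        assert pf.cross_derivation_correlations(a, b).loc["p", "p_r"] == pytest.approx(-1.0)

    def test_covariate_correlation_matches_regression_slope_oracle(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=2_000)
        c = 0.4 * f + rng.normal(size=2_000)
        scores = FactorScores(scores=pd.DataFrame({"p": f}))
        cov = pd.DataFrame({"VC": c})
        r = pf.covariate_correlations(scores, cov).loc["p", "VC_r"]
        slope = np.polyfit(f, c, 1)[0]
        r_oracle = slope * f.std(ddof=0) / c.std(ddof=0)
        assert r == pytest.approx(r_oracle, abs=1e-12)

    def test_independent_noise_not_significant(self):
        rng = np.random.default_rng(9)
        scores = FactorScores(scores=pd.DataFrame({"p": rng.normal(size=300)}))
        cov = pd.DataFrame({"VC": rng.normal(size=300)})
        table = pf.covariate_correlations(scores, cov)
        assert abs(table.loc["p", "VC_r"]) < 0.15
        assert table.loc["p", "VC_sig"] in ("", "*")

    def test_misaligned_rows_rejected(self):
        rng = np.random.default_rng(10)
        a = FactorScores(scores=pd.DataFrame({"p": rng.normal(size=100)}))
        with pytest.raises(ValueError):
            pf.covariate_correlations(a, pd.DataFrame({"VC": rng.normal(size=99)}))
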