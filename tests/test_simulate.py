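"""Skew-transform solver, intermediate correlations and the population generator."""

import numpy as np
import pytest
from scipy import stats

import pfactorlab as pf
from pfactorlab.simulate import FleishmanInfeasibleError, fleishman_coefficients, intermediate_correlation


def _transform(z, coeffs):
    a, b, c, d = coeffs
    return a + z * (b + z * (c + z * d))


class TestFleishman:
    def test_zero_moments_give_identity(self):
        assert fleishman_coefficients(0.0, 0.0) == (0.0, 1.0, 0.0, 0.0)

    def test_monte_carlo_moments_for_default_targets(self):
        coeffs = fleishman_coefficients(2.0, 7.0)
        z = np.random.default_rng(202).standard_normal(5_000_000)
        y = _transform(z, coeffs)
        assert y.mean() == pytest.approx(0.0, abs=0.01)
        assert y.var() == pytest.approx(1.0, abs=0.01)
        assert stats.skew(y) == pytest.approx(2.0, abs=0.05)
        assert stats.kurtosis(y) == pytest.approx(7.0, abs=0.4)

    def test_infeasible_moment_pair_raises(self):
        with pytest.raises(FleishmanInfeasibleError):
            fleishman_coefficients(3.0, 0.0)

    @pytest.mark.parametrize("skew,kurt", [(1.0, 2.0), (2.0, 7.0), (-1.5, 4.0), (0.0, 3.0)])
    def test_solution_satisfies_moment_equations(self, skew, kurt):
        a, b, c, d = fleishman_coefficients(skew, kurt)
        assert a == pytest.approx(-c, abs=1e-12)
        var = b * b + 6 * b * d + 2 * c * c + 15 * d * d
        sk = 2 * c * (b * b + 24 * b * d + 105 * d * d + 2)
        assert var == pytest.approx(1.0, abs=1e-9)
        assert sk == pytest.approx(skew, abs=1e-9)


class TestIntermediateCorrelation:
    def test_zero_target_maps_to_zero(self):
        coeffs = fleishman_coefficients(2.0, 7.0)
        assert intermediate_correlation(0.0, coeffs, coeffs) == pytest.approx(0.0, abs=1e-12)

    def test_unit_target_with_identical_margins(self):
        coeffs = fleishman_coefficients(2.0, 7.0)
        assert intermediate_correlation(1.0, coeffs, coeffs) == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_post_transform_correlation(self):
        # mania-schiz implied correlation under the original generating set
        target = 0.973 * 0.819
        coeffs = fleishman_coefficients(2.0, 7.0)
        rho = intermediate_correlation(target, coeffs, coeffs)
        assert rho > target  # correction inflates the pre-transform value
        rng = np.random.default_rng(7)
        z1 = rng.standard_normal(1_000_000)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(1_000_000)
        r = np.corrcoef(_transform(z1, coeffs), _transform(z2, coeffs))[0, 1]
        assert r == pytest.approx(target, abs=0.01)

    def test_out_of_range_target_rejected(self):
        coeffs = fleishman_coefficients(1.0, 2.0)
        with pytest.raises(ValueError):
            intermediate_correlation(1.5, coeffs, coeffs)


class TestMarginalSkewness:
    def test_symmetric_input_is_zero(self):
        assert pf.marginal_skewness(np.array([-1.0, 0.0, 1.0])) == 0.0

    def test_exponential_sample_close_to_two(self):
        x = np.random.default_rng(5).exponential(1.0, 1_000_000)
        assert pf.marginal_skewness(x) == pytest.approx(2.0, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pf.marginal_skewness(np.ones(100))
        with pytest.raises(ValueError):
            pf.marginal_skewness(np.array([1.0, 2.0]))


class TestGenerator:
    def test_seed_determinism(self):
        cfg = pf.SimulationConfig(n_subjects=2_000, seed=99)
        a = pf.generate_population(cfg)
        b = pf.generate_population(pf.SimulationConfig(n_subjects=2_000, seed=99))
        assert a.symptoms.equals(b.symptoms)
        assert a.covariates.equals(b.covariates)
        assert a.latent_scores.equals(b.latent_scores)

    def test_marginal_skew_near_target(self, small_population):
        sk = [pf.marginal_skewness(small_population.symptoms[c].to_numpy())
              for c in small_population.symptoms]
        assert np.mean(sk) == pytest.approx(2.0, abs=0.1)

    def test_zero_skew_mode_is_multivariate_normal(self, caspi_params, spec_c):
        cfg = pf.SimulationConfig(n_subjects=100_000, seed=3, target_skew=0.0,
                                  target_excess_kurtosis=0.0)
        pop = pf.generate_population(cfg)
        sk = [pf.marginal_skewness(pop.symptoms[c].to_numpy()) for c in pop.symptoms]
        assert np.max(np.abs(sk)) < 0.05
        implied = pf.implied_covariance(spec_c, caspi_params)
        r = np.corrcoef(pop.symptoms.to_numpy(), rowvar=False)
        assert np.abs(r - implied).max() < 0.02

    def test_correlation_fidelity_with_skew(self, small_population, caspi_params, spec_c):
        implied = pf.implied_covariance(spec_c, caspi_params)
        r = np.corrcoef(small_population.symptoms.to_numpy(), rowvar=False)
        assert np.abs(r - implied).max() < 0.035  # n = 20,000 sampling tolerance

    def test_naive_mode_attenuates_correlations(self, caspi_params, spec_c):
        cfg = pf.SimulationConfig(n_subjects=50_000, seed=21, correct_intermediate=False)
        pop = pf.generate_population(cfg)
        implied = pf.implied_covariance(spec_c, caspi_params)
        r = np.corrcoef(pop.symptoms.to_numpy(), rowvar=False)
        i, j = np.tril_indices(11, -1)
        # uncorrected transform shrinks correlations toward zero on average
        assert np.mean(np.abs(r[i, j])) < np.mean(np.abs(implied[i, j])) * 0.97

    def test_covariates_normal_with_target_scale(self, small_population):
        cov = small_population.covariates
        assert np.allclose(cov.mean(), 100.0, atol=0.5)
        assert np.allclose(cov.std(ddof=0), 15.0, atol=0.5)
        for c in cov:
            assert abs(pf.marginal_skewness(cov[c].to_numpy())) < 0.07

    def test_covariate_factor_correlations_match_targets(self, small_population):
        targets = pf.covariate_targets("caspi")
        lat = small_population.latent_scores
        for f in ("p", "Ext", "Int"):
            for c in ("VC", "PR", "WM", "PS"):
                r = np.corrcoef(lat[f], small_population.covariates[c])[0, 1]
                assert r == pytest.approx(targets.loc[f, c], abs=0.025)

    def test_covariate_weights_match_least_squares_oracle(self, small_population, caspi_params):
        # solving the 3x3 system must equal brute-force least squares of the
        # target correlation vector on the latent correlation matrix
        targets = pf.covariate_targets("caspi")["WM"].to_numpy()
        phi = caspi_params.factor_correlations
        w_solve = np.linalg.solve(phi, targets)
        w_lstsq, *_ = np.linalg.lstsq(phi, targets, rcond=None)
        assert np.allclose(w_solve, w_lstsq, atol=1e-10)

    def test_all_zero_targets_give_pure_noise_covariate(self, caspi_params):
        import pandas as pd
        from pfactorlab.simulate import CovariateSpec, generate_covariates

        rng = np.random.default_rng(0)
        lat = pd.DataFrame(rng.standard_normal((30_000, 3)), columns=["p", "Ext", "Int"])
        spec = CovariateSpec(target_correlations=pd.DataFrame(
            0.0, index=["p", "Ext", "Int"], columns=["VC", "PR", "WM", "PS"]))
        cov = generate_covariates(lat, spec, np.eye(3), rng)
        for f in ("p", "Ext", "Int"):
            assert abs(np.corrcoef(lat[f], cov["VC"])[0, 1]) < 0.02

    def test_infeasible_covariate_targets_rejected(self):
        import pandas as pd
        from pfactorlab.simulate import CovariateSpec, generate_covariates

        rng = np.random.default_rng(0)
        lat = pd.DataFrame(rng.standard_normal((100, 3)), columns=["p", "Ext", "Int"])
        spec = CovariateSpec(target_correlations=pd.DataFrame(
            0.7, index=["p", "Ext", "Int"], columns=["VC", "PR", "WM", "PS"]))
        with pytest.raises(ValueError, match="R\\^2"):
            generate_covariates(lat, spec, np.eye(3), rng)

    def test_csv_round_trip(self, tmp_path):
        from pfactorlab.simulate import read_population_csv

        pop = pf.generate_population(pf.SimulationConfig(n_subjects=500, seed=1))
        path = tmp_path / "pop.csv"
        pop.write_csv(path)
        sym, cov = read_population_csv(path)
        assert np.allclose(sym.to_numpy(), pop.symptoms.to_numpy())
        assert np.allclose(cov.to_numpy(), pop.covariates.to_numpy())
        assert path.with_suffix(".config.json").exists()

    def test_skew_jitter_stays_feasible(self):
        cfg = pf.SimulationConfig(n_subjects=1_000, seed=4, skew_jitter_sd=0.35)
        pop = pf.generate_population(cfg)  # must not raise infeasibility
        assert pop.symptoms.shape == (1_000, 11)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            pf.SimulationConfig(n_subjects=1)
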