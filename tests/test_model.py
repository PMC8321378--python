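import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from spagen import model, synth
from spagen.errors import FittingError
from spagen.geometry import GLAUCOMA, HEALTHY
from spagen.model import ModelConfig, SpaGenParams


def _flat_params(**overrides):
    base = dict(beta0=0.4, beta_g0=0.2, beta_cdar=0.5,
                fourier_g=np.zeros(4), fourier_h=np.zeros(4),
                sigma_z2=0.01, sigma_g2=0.04, sigma_h2=0.02, prior_g=0.3)
    base.update(overrides)
    return SpaGenParams(**base)


class TestParameterCounting:
    @pytest.mark.parametrize("use_cdar,n_var,expected", [
        (True, 2, 15),   # full model: 1 prior + 11 fixed + 3 variances
        (False, 1, 13),
        (False, 2, 14),
        (True, 1, 14),
    ])
    def test_counts_match_model_accounting(self, use_cdar, n_var, expected):
        cfg = ModelConfig(use_cdar=use_cdar, n_variances=n_var)
        assert model.count_parameters(cfg) == expected

    def test_fit_records_count(self, fitted_model):
        assert fitted_model.n_params == model.count_parameters(fitted_model.config)


class TestMeanVector:
    def test_constants_only_glaucoma(self):
        mu = model.mean_vector(_flat_params(), GLAUCOMA, cdar=0.2)
        np.testing.assert_allclose(mu, 0.7)

    def test_constants_only_healthy(self):
        mu = model.mean_vector(_flat_params(), HEALTHY, cdar=0.2)
        np.testing.assert_allclose(mu, 0.5)

    def test_cosine_harmonic_shifts_last_direction(self):
        # beta_H,2 multiplies cos(2*pi*d/24): at d = 24 the factor is 1
        p = _flat_params(beta0=0.5, beta_g0=0.0, beta_cdar=None,
                         fourier_h=np.array([0.0, 0.1, 0.0, 0.0]))
        mu = model.mean_vector(p, HEALTHY)
        assert mu[-1] == pytest.approx(0.6, abs=1e-12)
        assert mu.mean() == pytest.approx(0.5, abs=1e-12)

    def test_missing_cdar_rejected_when_model_uses_it(self):
        with pytest.raises(ValueError):
            model.mean_vector(_flat_params(), GLAUCOMA, cdar=None)


class TestCovariance:
    def test_diagonal_when_no_random_effect(self):
        v = model.covariance_matrix(_flat_params(sigma_z2=0.0), GLAUCOMA)
        np.testing.assert_allclose(v, 0.04 * np.eye(24))

    def test_compound_symmetry_entries_and_eigenvalues(self):
        v = model.covariance_matrix(_flat_params(sigma_g2=0.04), GLAUCOMA)
        assert v[0, 0] == pytest.approx(0.05)
        assert v[0, 1] == pytest.approx(0.01)
        eig = np.sort(np.linalg.eigvalsh(v))
        np.testing.assert_allclose(eig[:-1], 0.04, atol=1e-10)
        assert eig[-1] == pytest.approx(0.04 + 24 * 0.01, abs=1e-10)

    def test_single_variance_config_shares_matrices(self):
        p = _flat_params(sigma_h2=0.04)
        vg = model.covariance_matrix(p, GLAUCOMA)
        vh = model.covariance_matrix(p, HEALTHY)
        np.testing.assert_allclose(vg, vh)


class TestLogDensity:
    def test_univariate_standard_normal(self):
        mom = model.GroupMoments(mean=np.zeros(1), cov=np.eye(1),
                                 sigma2=1.0, sigma_z2=0.0)
        assert model.log_density(np.zeros(1), mom) == pytest.approx(
            -0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            sz2 = float(rng.uniform(0.0, 0.05))
            s2 = float(rng.uniform(1e-3, 0.1))
            mu = rng.normal(0.5, 0.1, n)
            cov = sz2 * np.ones((n, n)) + s2 * np.eye(n)
            mom = model.GroupMoments(mean=mu, cov=cov, sigma2=s2, sigma_z2=sz2)
            y = rng.normal(0.5, 0.2, n)
            dense = multivariate_normal(mean=mu, cov=cov).logpdf(y)
            assert model.log_density(y, mom) == pytest.approx(dense, abs=1e-8)

    def test_density_is_maximal_at_the_mean(self):
        rng = np.random.default_rng(3)
        mu = rng.normal(0.5, 0.1, 24)
        mom = model.GroupMoments(mean=mu, cov=None, sigma2=0.02, sigma_z2=0.01)
        at_mean = model.log_density(mu, mom)
        for _ in range(20):
            assert model.log_density(mu + rng.normal(0, 0.05, 24), mom) <= at_mean


class TestFitting:
    def test_fixed_effects_recovered_within_3_se(self, fitted_model):
        truth = synth.default_generating_params()
        est, se = fitted_model.params, fitted_model.se
        assert abs(est.beta0 - truth.beta0) <= 3 * se["beta0"]
        assert abs(est.beta_g0 - truth.beta_g0) <= 3 * se["beta_g0"]
        assert abs(est.beta_cdar - truth.beta_cdar) <= 3 * se["beta_cdar"]
        names = ["beta_g_sin1", "beta_g_cos1", "beta_g_sin2", "beta_g_cos2"]
        for i, nm in enumerate(names):
            assert abs(est.fourier_g[i] - truth.fourier_g[i]) <= 3 * se[nm]
        for i, nm in enumerate(n.replace("_g_", "_h_") for n in names):
            assert abs(est.fourier_h[i] - truth.fourier_h[i]) <= 3 * se[nm]

    def test_variance_components_within_20_percent(self, fitted_model):
        truth = synth.default_generating_params()
        est = fitted_model.params
        for name in ("sigma_z2", "sigma_g2", "sigma_h2"):
            t, e = getattr(truth, name), getattr(est, name)
            assert abs(e - t) / t <= 0.20
        assert fitted_model.converged

    def test_zero_random_effect_recovered_at_boundary(self):
        params = synth.default_generating_params()
        params.sigma_z2 = 0.0
        cohort = synth.sample_profiles(synth.SynthProfileConfig(
            params=params, n_eyes=1000, seed=5))
        fit = model.fit_ml(list(cohort), ModelConfig())
        assert fit.params.sigma_z2 <= 0.005

    def test_duplicating_eyes_doubles_loglik_not_estimates(self, training_cohort,
                                                           fitted_model):
        doubled = list(training_cohort) + list(training_cohort)
        fit2 = model.fit_ml(doubled, ModelConfig())
        assert fit2.loglik == pytest.approx(2 * fitted_model.loglik, rel=1e-4)
        assert fit2.params.beta0 == pytest.approx(fitted_model.params.beta0, abs=1e-4)
        assert fit2.params.sigma_g2 == pytest.approx(fitted_model.params.sigma_g2,
                                                     rel=1e-3)

    def test_missing_group_raises(self, training_cohort):
        healthy_only = [p for p in training_cohort if p.label == HEALTHY]
        with pytest.raises(FittingError):
            model.fit_ml(healthy_only, ModelConfig())

    def test_prior_defaults_to_prevalence(self, training_cohort, fitted_model):
        prev = np.mean([p.label == GLAUCOMA for p in training_cohort])
        assert fitted_model.params.prior_g == pytest.approx(prev)


class TestClassification:
    def test_equal_moments_give_prior(self):
        p = _flat_params(beta_g0=0.0, sigma_h2=0.04, prior_g=0.5)
        fit = model.SpaGenFit(config=ModelConfig(n_variances=1), params=p,
                              loglik=0.0, converged=True, n_params=14)
        y = np.random.default_rng(0).normal(0.6, 0.1, 24)
        assert model.posterior_glaucoma(y, 0.2, fit) == pytest.approx(0.5, abs=1e-12)

    def test_posterior_increasing_in_prior(self, fitted_model):
        rng = np.random.default_rng(1)
        y = rng.normal(0.55, 0.1, 24)
        posts = []
        for prior in (0.1, 0.3, 0.6, 0.9):
            fit = model.SpaGenFit(
                config=fitted_model.config,
                params=SpaGenParams(**{**fitted_model.params.__dict__,
                                       "prior_g": prior}),
                loglik=0.0, converged=True, n_params=fitted_model.n_params)
            p = model.posterior_glaucoma(y, 0.4, fit)
            assert 0.0 <= p <= 1.0
            posts.append(p)
        assert all(a < b for a, b in zip(posts, posts[1:]))

    def test_posterior_matches_dense_bayes_ratio(self, fitted_model):
        rng = np.random.default_rng(9)
        pg = fitted_model.params.prior_g
        for _ in range(25):
            y = rng.normal(0.5, 0.15, 24)
            cdar = float(rng.uniform(0.1, 0.9))
            mg = fitted_model.moments(GLAUCOMA, cdar)
            mh = fitted_model.moments(HEALTHY, cdar)
            fg = multivariate_normal(mean=mg.mean, cov=mg.cov).pdf(y)
            fh = multivariate_normal(mean=mh.mean, cov=mh.cov).pdf(y)
            expected = pg * fg / (pg * fg + (1 - pg) * fh)
            assert model.posterior_glaucoma(y, cdar, fitted_model) == pytest.approx(
                expected, abs=1e-10)

    def test_rds_at_healthy_mean_is_nonpositive(self, fitted_model):
        mh = fitted_model.moments(HEALTHY, 0.3)
        mg = fitted_model.moments(GLAUCOMA, 0.3)
        val = model.rds(mh.mean, 0.3, fitted_model)
        assert val <= 0.0
        assert val == pytest.approx(-0.5 * model.mahalanobis_sq(mh.mean, mg),
                                    abs=1e-10)

    def test_rds_equals_prior_adjusted_log_odds_with_shared_variance(self):
        params = synth.default_generating_params()
        params.sigma_h2 = params.sigma_g2
        fit = model.SpaGenFit(config=ModelConfig(n_variances=1), params=params,
                              loglik=0.0, converged=True, n_params=14)
        rng = np.random.default_rng(21)
        pg = params.prior_g
        for _ in range(100):
            y = rng.normal(0.5, 0.15, 24)
            cdar = float(rng.uniform(0.1, 0.9))
            p = model.posterior_glaucoma(y, cdar, fit)
            log_odds = math.log(p / (1 - p) * (1 - pg) / pg)
            assert model.rds(y, cdar, fit) == pytest.approx(log_odds, abs=1e-8)

    def test_equivalent_decision_rules_under_shared_variance(self):
        params = synth.default_generating_params()
        params.sigma_h2 = params.sigma_g2
        fit = model.SpaGenFit(config=ModelConfig(n_variances=1), params=params,
                              loglik=0.0, converged=True, n_params=14)
        p_th = 0.4
        rds_th = model.rds_threshold_from_posterior(p_th, params.prior_g)
        cohort = synth.sample_profiles(synth.SynthProfileConfig(
            params=params, n_eyes=200, seed=17))
        for prof in cohort:
            by_post = model.classify(
                model.posterior_glaucoma(prof.values, prof.cdar, fit), p_th)
            by_rds = model.classify(
                model.rds(prof.values, prof.cdar, fit), rds_th, kind="rds")
            assert by_post == by_rds

    def test_identical_group_moments_give_zero_rds(self):
        p = _flat_params(beta_g0=0.0, sigma_h2=0.04)
        fit = model.SpaGenFit(config=ModelConfig(n_variances=1), params=p,
                              loglik=0.0, converged=True, n_params=14)
        y = np.random.default_rng(2).normal(0.5, 0.1, 24)
        assert model.rds(y, 0.3, fit) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("score,thr,expected", [
        (0.7, 0.5, GLAUCOMA),
        (0.5, 0.5, GLAUCOMA),  # boundary: >= rule
        (0.3, 0.5, HEALTHY),
    ])
    def test_threshold_rule(self, score, thr, expected):
        assert model.classify(score, thr) == expected


class TestSerialization:
    def test_json_round_trip_preserves_scores(self, tmp_path, fitted_model):
        path = tmp_path / "fit.json"
        model.fit_to_json(fitted_model, path)
        back = model.fit_from_json(path)
        assert back.n_params == fitted_model.n_params
        assert back.config == fitted_model.config
        y = np.random.default_rng(4).normal(0.5, 0.1, 24)
        assert model.posterior_glaucoma(y, 0.4, back) == pytest.approx(
            model.posterior_glaucoma(y, 0.4, fitted_model), abs=1e-12)
        assert model.rds(y, 0.4, back) == pytest.approx(
            model.rds(y, 0.4, fitted_model), abs=1e-10)


class TestCdarBaseline:
    def test_baseline_sits_between_chance_and_full_model(self, training_cohort,
                                                         fitted_model):
        from spagen import metrics

        test = synth.sample_profiles(synth.SynthProfileConfig(n_eyes=800, seed=88))
        labels = np.array([p.label == GLAUCOMA for p in test])
        baseline = model.fit_cdar_baseline(list(training_cohort))
        auc_cdar = metrics.roc_auroc(baseline.score([p.cdar for p in test]), labels)
        full = np.array([model.posterior_glaucoma(p.values, p.cdar, fitted_model)
                         for p in test])
        auc_full = metrics.roc_auroc(full, labels)
        assert 0.5 < auc_cdar < auc_full
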