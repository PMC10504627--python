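import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm

from conftest import make_separated_config
from phenorisk.preprocess import DailyFeatureMatrix
from phenorisk.profiling import (BERNOULLI_EPS, VARIANCE_FLOOR,
                                 HeterogeneousMixtureModel,
                                 InsufficientDataError,
                                 bic_score, day_loglik, em_fit,
                                 select_profiles, split_features)
from phenorisk.synthetic import sample_feature_matrix


def toy_model(K=2, C=1, B=1, **overrides):
    params = dict(
        weights=np.full(K, 1.0 / K),
        cont_means=np.linspace(0, 3, K)[:, None] * np.ones((K, C)),
        cont_vars=np.ones((K, C)),
        bern_probs=np.linspace(0.1, 0.9, K)[:, None] * np.ones((K, B)),
    )
    params.update(overrides)
    return HeterogeneousMixtureModel(**params)


def random_features(n_days=30, seed=0, missing_frac=0.0) -> DailyFeatureMatrix:
    rng = np.random.default_rng(seed)
    mask = rng.random((n_days, 4, 48)) >= missing_frac
    return DailyFeatureMatrix(
        patient_id="T", days=np.arange(n_days),
        distance=rng.normal(3, 1, (n_days, 48)).clip(0),
        home=(rng.random((n_days, 48)) < 0.6).astype(float),
        steps=rng.normal(4, 1, (n_days, 48)).clip(0),
        app=(rng.random((n_days, 48)) < 0.4).astype(float),
        mask=mask)


def align_components(true_means, fitted_means):
    cost = np.linalg.norm(true_means[:, None, :] - fitted_means[None, :, :], axis=2)
    _, cols = linear_sum_assignment(cost)
    return cols


class TestDayLoglik:
    def test_all_dims_missing_gives_zero_for_every_component(self):
        m = toy_model()
        ll = day_loglik(m, (np.zeros(1), np.zeros(1)),
                        (np.zeros(1, bool), np.zeros(1, bool)))
        np.testing.assert_allclose(ll, [0.0, 0.0])

    def test_single_component_posterior_is_one(self):
        m = toy_model(K=1, weights=np.array([1.0]))
        ll = day_loglik(m, (np.array([2.0]), np.array([1.0])))
        assert ll.shape == (1,)

    def test_two_component_bayes_rule_by_hand(self):
        # Gaussian dim mu={0,3}, var=1; Bernoulli dim p={0.1,0.9};
        # observation (3, 1); equal weights. Oracle: direct Bayes rule.
        m = toy_model(K=2, cont_means=np.array([[0.0], [3.0]]),
                      cont_vars=np.array([[1.0], [1.0]]),
                      bern_probs=np.array([[0.1], [0.9]]))
        lik = np.array([norm.pdf(3, 0, 1) * 0.1, norm.pdf(3, 3, 1) * 0.9])
        expected = lik / lik.sum()
        ll = day_loglik(m, (np.array([3.0]), np.array([1.0])))
        post = np.exp(ll) * m.weights
        post /= post.sum()
        np.testing.assert_allclose(post, expected, rtol=1e-9)

    def test_partial_missingness_marginalizes_exactly(self):
        m = toy_model(K=2, C=2, B=2)
        full_obs = (np.array([1.0, 2.0]), np.array([1.0, 0.0]))
        ll_one_dim = day_loglik(m, full_obs,
                                (np.array([True, False]), np.array([False, False])))
        # equals the loglik computed on a 1-continuous-dim model
        m1 = toy_model(K=2, C=1, B=1)
        ll_ref = day_loglik(m1, (np.array([1.0]), np.array([0.0])),
                            (np.array([True]), np.array([False])))
        np.testing.assert_allclose(ll_one_dim, ll_ref, rtol=1e-12)


class TestEmFit:
    def test_k1_closed_form_mle(self):
        feats = random_features(n_days=25, seed=1, missing_frac=0.2)
        model = em_fit(feats, K=1, n_restarts=1, seed=0)
        xc, mc, xb, mb = split_features(feats)
        mean_oracle = np.where(mc, xc, 0).sum(0) / mc.sum(0)
        var_oracle = np.maximum(
            np.where(mc, (xc - mean_oracle) ** 2, 0).sum(0) / mc.sum(0), VARIANCE_FLOOR)
        p_oracle = np.clip(np.where(mb, xb, 0).sum(0) / mb.sum(0),
                           BERNOULLI_EPS, 1 - BERNOULLI_EPS)
        np.testing.assert_allclose(model.weights, [1.0])
        np.testing.assert_allclose(model.cont_means[0], mean_oracle, rtol=1e-6)
        np.testing.assert_allclose(model.cont_vars[0], var_oracle, rtol=1e-5)
        np.testing.assert_allclose(model.bern_probs[0], p_oracle, rtol=1e-6)

    def test_loglik_monotone_over_iterations(self):
        feats, _ = sample_feature_matrix(make_separated_config(2, days=60, seed=3), 0)
        _, history = em_fit(feats, K=2, n_restarts=2, seed=1, return_history=True)
        h = np.asarray(history)
        assert np.all(np.diff(h) >= -1e-7 * np.abs(h[:-1]))

    def test_recovers_separated_means(self):
        cfg = make_separated_config(2, days=120, seed=4)
        feats, _ = sample_feature_matrix(cfg, 0)
        model = em_fit(feats, K=2, seed=2)
        true_means = np.array([
            np.concatenate([p.distance_log_mean, p.steps_log_mean])
            for p in cfg.profile_emission_params])
        cols = align_components(true_means, model.cont_means)
        err = np.abs(model.cont_means[cols] - true_means).max()
        assert err < 0.1

    def test_duplicated_days_are_a_fixed_point(self):
        feats = random_features(n_days=20, seed=5)
        model = em_fit(feats, K=2, seed=3)
        doubled = DailyFeatureMatrix(
            patient_id="T", days=np.arange(40),
            distance=np.vstack([feats.distance] * 2), home=np.vstack([feats.home] * 2),
            steps=np.vstack([feats.steps] * 2), app=np.vstack([feats.app] * 2),
            mask=np.vstack([feats.mask] * 2))
        refit = em_fit(doubled, K=2, init_model=model, max_iter=1, seed=0)
        np.testing.assert_allclose(refit.cont_means, model.cont_means, atol=1e-4)
        np.testing.assert_allclose(refit.weights, model.weights, atol=1e-5)

    def test_insufficient_days_raises(self):
        feats = random_features(n_days=3)
        with pytest.raises(InsufficientDataError):
            em_fit(feats, K=5)


class TestBic:
    def test_penalty_prefers_k1_on_single_cluster(self):
        feats, _ = sample_feature_matrix(make_separated_config(1, days=80, seed=6), 0)
        m1 = em_fit(feats, K=1, seed=0)
        m2 = em_fit(feats, K=2, seed=0)
        assert bic_score(m1, feats) < bic_score(m2, feats)

    def test_duplicate_parameterization_strictly_worse(self):
        feats = random_features(n_days=15, seed=7)
        m1 = em_fit(feats, K=1, seed=0)
        dup = HeterogeneousMixtureModel(
            weights=np.array([0.5, 0.5]),
            cont_means=np.vstack([m1.cont_means] * 2),
            cont_vars=np.vstack([m1.cont_vars] * 2),
            bern_probs=np.vstack([m1.bern_probs] * 2))
        assert bic_score(dup, feats) > bic_score(m1, feats)

    def test_single_day_bic_is_minus_two_loglik(self):
        feats = random_features(n_days=1, seed=8)
        m = em_fit(feats, K=1, n_restarts=1, seed=0)
        xc, mc, xb, mb = split_features(feats)
        from phenorisk.profiling import _responsibilities
        _, ll = _responsibilities(m, xc, mc, xb, mb)
        assert bic_score(m, feats) == pytest.approx(-2 * ll)  # log(1) = 0


class TestSelectProfiles:
    def test_recovers_k3_on_separated_data(self):
        feats, _ = sample_feature_matrix(make_separated_config(3, days=120, seed=9), 0)
        model, post = select_profiles(feats, K_max=6, seed=1)
        assert model.n_components == 3
        assert post.probs.shape == (120, 3)

    def test_constant_days_select_k1(self):
        n = 30
        feats = DailyFeatureMatrix(
            patient_id="T", days=np.arange(n),
            distance=np.full((n, 48), 2.0), home=np.ones((n, 48)),
            steps=np.full((n, 48), 3.0), app=np.zeros((n, 48)),
            mask=np.ones((n, 4, 48), dtype=bool))
        model, _ = select_profiles(feats, K_max=3, seed=0)
        assert model.n_components == 1

    def test_kmax_one_degenerate_posterior(self):
        feats = random_features(n_days=10, seed=10)
        model, post = select_profiles(feats, K_max=1, seed=0)
        np.testing.assert_allclose(post.probs, 1.0)

    def test_fully_missing_rows_equal_weights_exactly(self):
        feats = random_features(n_days=20, seed=11)
        feats.mask[5] = False
        feats.mask[11] = False
        model, post = select_profiles(feats, K_max=2, seed=0)
        np.testing.assert_array_equal(post.probs[5], model.weights)
        np.testing.assert_array_equal(post.probs[11], model.weights)
        assert post.missing[5] and post.missing[11]

    def test_posterior_rows_on_simplex(self):
        feats = random_features(n_days=25, seed=12, missing_frac=0.3)
        _, post = select_profiles(feats, K_max=3, seed=0)
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)


class TestPermutationInvariance:
    def test_relabeling_leaves_bic_and_posteriors_permuted(self):
        feats, _ = sample_feature_matrix(make_separated_config(2, days=40, seed=13), 0)
        model = em_fit(feats, K=2, seed=5)
        perm = model.permuted([1, 0])
        assert bic_score(model, feats) == pytest.approx(bic_score(perm, feats), rel=1e-12)
        xc, mc, xb, mb = split_features(feats)
        from phenorisk.profiling import _responsibilities
        r1, _ = _responsibilities(model, xc, mc, xb, mb)
        r2, _ = _responsibilities(perm, xc, mc, xb, mb)
        np.testing.assert_allclose(r1, r2[:, [1, 0]], rtol=1e-9)


class TestModelSerialization:
    def test_json_roundtrip(self):
        m = toy_model(K=3, C=4, B=2)
        again = HeterogeneousMixtureModel.from_json(m.to_json())
        np.testing.assert_allclose(again.cont_means, m.cont_means)
        np.testing.assert_allclose(again.weights, m.weights)
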