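import numpy as np
import pytest

from capritrack.hmm import (
    EstrusBehaviorHMM,
    GMMEmission,
    HMMModel,
    PosteriorMatrix,
    TransitionMatrix,
    backward_smooth,
    brute_force_posterior,
    decode_map,
    emission_logdensity,
    estimate_transition_matrix,
    fit_state_gmm,
    forward_filter,
    gmm_n_parameters,
    load_model,
    select_gmm_components_aic,
    smooth,
)
from capritrack.simulate import recovery_config, simulate_cohort, simulate_states

from conftest import make_random_model, make_separated_model


class TestTransitionEstimation:
    def test_hand_counted_six_transitions(self):
        tr = estimate_transition_matrix([[0, 0, 1, 1, 2, 2, 0]])
        expected = np.array([[0.5, 0.5, 0], [0, 0.5, 0.5], [0.5, 0, 0.5]])
        np.testing.assert_allclose(tr.T, expected, atol=1e-9)
        np.testing.assert_allclose(tr.pi, [1, 0, 0])

    def test_unseen_states_get_uniform_rows(self):
        tr = estimate_transition_matrix([[1, 1, 1, 1]])
        np.testing.assert_allclose(tr.T[1], [0, 1, 0], atol=1e-9)
        np.testing.assert_allclose(tr.T[0], np.full(3, 1 / 3), atol=1e-9)
        np.testing.assert_allclose(tr.T[2], np.full(3, 1 / 3), atol=1e-9)

    def test_rows_are_probability_vectors(self):
        tr = estimate_transition_matrix([[0, 1, 2, 0, 2, 1]])
        np.testing.assert_allclose(tr.T.sum(axis=1), 1.0, atol=1e-12)
        assert (tr.T > 0).all()  # epsilon-floored

    def test_long_chain_recovers_truth(self, rng):
        T = np.array([[0.8, 0.15, 0.05], [0.1, 0.7, 0.2], [0.05, 0.25, 0.7]])
        truth = TransitionMatrix(T=T, pi=np.array([0.3, 0.3, 0.4]))
        chain = simulate_states(truth, 100_000, rng)
        est = estimate_transition_matrix([chain])
        assert np.abs(est.T - T).max() < 0.02

    def test_pooling_over_sequences(self):
        pooled = estimate_transition_matrix([[0, 1], [1, 2], [2, 0]])
        np.testing.assert_allclose(pooled.T[0], [0, 1, 0], atol=1e-9)
        np.testing.assert_allclose(pooled.pi, [1 / 3, 1 / 3, 1 / 3])

    @pytest.mark.parametrize("bad", [[], [[0, 5, 1]]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            estimate_transition_matrix(bad)


class TestGMMEmissions:
    def test_aic_bookkeeping(self):
        assert gmm_n_parameters(1) == 6
        assert gmm_n_parameters(10) == 69
        # loglik = -100 at m=1 -> AIC = 200 + 12 = 212
        em = GMMEmission(0, 1, [1.0], np.zeros((1, 3)), np.ones((1, 3)), -100.0, 0.0)
        assert -2 * em.loglik + 2 * gmm_n_parameters(em.m) == pytest.approx(212.0)

    def test_single_gaussian_mean_recovery(self, rng):
        X = rng.normal([1.0, -2.0, 3.0], 1.0, size=(5000, 3))
        em = fit_state_gmm(X, m=1, seed=0)
        assert em.aic == pytest.approx(-2 * em.loglik + 2 * 6)
        np.testing.assert_allclose(em.means[0], [1.0, -2.0, 3.0], atol=0.05)

    def test_zero_variance_coordinate_is_floored(self, rng):
        X = rng.normal(size=(200, 3))
        X[:, 2] = 0.7  # degenerate coordinate
        em = fit_state_gmm(X, m=1, seed=0)
        assert (em.variances >= 1e-6).all()
        assert np.isfinite(em.logpdf(np.array([0.0, 0.0, 0.7])))

    def test_infeasible_component_count(self):
        with pytest.raises(ValueError):
            fit_state_gmm(np.zeros((2, 3)), m=5)

    def test_aic_selects_one_component_for_unimodal_data(self, rng):
        X = rng.normal(0.0, 1.0, size=(5000, 3))
        em = select_gmm_components_aic(X, m_grid=range(1, 6), seed=0)
        assert em.m == 1

    def test_aic_selects_two_for_separated_bimodal_data(self, rng):
        X = np.vstack(
            [rng.normal(0.0, 1.0, (2500, 3)), rng.normal(12.0, 1.0, (2500, 3))]
        )
        em = select_gmm_components_aic(X, m_grid=range(1, 6), seed=0)
        assert em.m == 2

    def test_singleton_grid_is_unconditional(self, rng):
        X = rng.normal(size=(100, 3))
        assert select_gmm_components_aic(X, m_grid=[1], seed=0).m == 1

    def test_infeasible_grid_entries_skipped(self, rng):
        X = rng.normal(size=(4, 3))
        with pytest.warns(UserWarning, match="skipping"):
            em = select_gmm_components_aic(X, m_grid=[2, 50], seed=0)
        assert em.m == 2


class TestEmissionDensity:
    def test_gaussian_mode_value(self):
        em = GMMEmission(0, 1, [1.0], np.zeros((1, 3)), np.ones((1, 3)), 0.0, 0.0)
        model = HMMModel(
            TransitionMatrix(np.eye(3) * 0 + 1 / 3, np.full(3, 1 / 3)),
            (em, GMMEmission(1, 1, [1.0], np.ones((1, 3)), np.ones((1, 3)), 0, 0),
             GMMEmission(2, 1, [1.0], 2 * np.ones((1, 3)), np.ones((1, 3)), 0, 0)),
        )
        assert emission_logdensity(model, np.zeros(3), 0) == pytest.approx(
            np.log((2 * np.pi) ** -1.5)
        )

    def test_mixture_of_identical_components_collapses(self):
        mu, var = np.array([[1.0, 2.0, 3.0]]), np.array([[0.5, 0.5, 0.5]])
        single = GMMEmission(0, 1, [1.0], mu, var, 0.0, 0.0)
        double = GMMEmission(
            0, 2, [0.5, 0.5], np.vstack([mu, mu]), np.vstack([var, var]), 0.0, 0.0
        )
        z = np.array([0.3, 1.4, 2.8])
        assert float(double.logpdf(z)) == pytest.approx(float(single.logpdf(z)))

    def test_density_integrates_to_one_by_quadrature(self):
        em = GMMEmission(
            0,
            2,
            [0.4, 0.6],
            np.array([[0.0, 0.0, 0.0], [1.5, -1.0, 0.5]]),
            np.array([[0.3, 0.4, 0.5], [0.6, 0.3, 0.4]]),
            0.0,
            0.0,
        )
        g = np.linspace(-6, 7, 61)
        dx = g[1] - g[0]
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        total = np.exp(em.logpdf(pts)).sum() * dx**3
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_nonfinite_observation_rejected(self):
        em = GMMEmission(0, 1, [1.0], np.zeros((1, 3)), np.ones((1, 3)), 0.0, 0.0)
        with pytest.raises(ValueError):
            em.logpdf(np.array([np.nan, 0.0, 0.0]))


class TestRecursions:
    def test_uninformative_emissions_give_chain_marginals(self):
        model = make_separated_model(gap=0.0)  # identical emissions
        T, pi = model.transition.T, model.transition.pi
        Z = np.random.default_rng(0).normal(size=(6, 3))
        filt = forward_filter(model, Z)
        marg = pi.copy()
        for k in range(6):
            np.testing.assert_allclose(filt.probs[k], marg, atol=1e-12)
            marg = T.T @ marg
        sm = backward_smooth(model, filt)
        marg = pi.copy()
        for k in range(6):
            np.testing.assert_allclose(sm.probs[k], marg, atol=1e-12)
            marg = T.T @ marg

    def test_separated_emissions_decode_true_states(self, rng):
        model = make_separated_model(gap=20.0)
        states = simulate_states(model.transition, 200, rng)
        Z = rng.normal(0, 1, (200, 3)) + states[:, None] * 20.0
        decoded = decode_map(smooth(model, Z))
        np.testing.assert_array_equal(decoded, states)

    def test_k1_smoothed_equals_filtered_equals_bayes(self, rng):
        model = make_random_model(rng)
        Z = rng.normal(size=(1, 3))
        filt = forward_filter(model, Z)
        sm = backward_smooth(model, filt)
        np.testing.assert_allclose(sm.probs, filt.probs)
        logb = model.emission_logdensities(Z)[0]
        expected = model.transition.pi * np.exp(logb)
        expected /= expected.sum()
        np.testing.assert_allclose(filt.probs[0], expected, atol=1e-12)

    def test_matches_brute_force_over_random_instances(self, rng):
        worst = 0.0
        for _ in range(50):
            model = make_random_model(rng, m=int(rng.integers(1, 3)))
            K = int(rng.integers(2, 9))
            Z = rng.normal(0, 2, (K, 3))
            sm = smooth(model, Z)
            bf = brute_force_posterior(model, Z)
            worst = max(worst, float(np.abs(sm.probs - bf.probs).max()))
        assert worst < 1e-10

    def test_agrees_with_hmmlearn_posteriors(self, rng):
        # independent library cross-check on a longer sequence
        from hmmlearn.hmm import GMMHMM

        model = make_random_model(rng, m=2)
        Z = rng.normal(0, 2, (100, 3))
        h = GMMHMM(n_components=3, n_mix=2, covariance_type="diag", init_params="")
        h.startprob_ = model.transition.pi
        h.transmat_ = model.transition.T
        h.weights_ = np.vstack([e.weights for e in model.emissions])
        h.means_ = np.stack([e.means for e in model.emissions])
        h.covars_ = np.stack([e.variances for e in model.emissions])
        np.testing.assert_allclose(h.predict_proba(Z), smooth(model, Z).probs, atol=1e-10)
        assert forward_filter(model, Z).loglik == pytest.approx(h.score(Z))

    def test_scale_invariance_of_smoothing(self, rng):
        # multiplying every emission density at one frame by a constant
        # (adding a constant in log space) must leave posteriors unchanged
        model = make_random_model(rng)
        Z = rng.normal(size=(10, 3))
        base = smooth(model, Z).probs

        logb = model.emission_logdensities(Z)
        logb_scaled = logb + rng.normal(0, 5, size=(10, 1))

        class Shifted:
            transition = model.transition

            def emission_logdensities(self, _):
                return logb_scaled

        np.testing.assert_allclose(smooth(Shifted(), Z).probs, base, atol=1e-9)

    def test_posterior_rows_sum_to_one(self, rng):
        model = make_random_model(rng)
        Z = rng.normal(size=(300, 3))
        for post in (forward_filter(model, Z), smooth(model, Z)):
            np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_deterministic_chain_posterior_is_one_hot(self):
        model = make_separated_model(gap=0.0)
        model.transition.T = np.eye(3)
        model.transition.pi = np.array([0.0, 1.0, 0.0])
        sm = smooth(model, np.zeros((5, 3)))
        np.testing.assert_allclose(sm.probs, np.tile([0, 1, 0], (5, 1)), atol=1e-12)

    def test_brute_force_refuses_long_sequences(self, rng):
        model = make_random_model(rng)
        with pytest.raises(ValueError):
            brute_force_posterior(model, rng.normal(size=(11, 3)))


class TestDecodeMap:
    def test_one_hot_rows(self):
        probs = np.array([[1, 0, 0], [0, 0, 1], [0, 1, 0]], dtype=float)
        post = PosteriorMatrix(probs=probs, kind="smoothed")
        np.testing.assert_array_equal(decode_map(post), [0, 2, 1])

    def test_ties_break_to_smallest_state(self):
        post = PosteriorMatrix(probs=np.full((2, 3), 1 / 3), kind="smoothed")
        np.testing.assert_array_equal(decode_map(post), [0, 0])


class TestModelObjectAndSerialization:
    def test_fit_recovers_and_serializes_bit_exactly(self, tmp_path, rng):
        cfg = recovery_config(seed=7, n_frames=200)
        trajs, _ = simulate_cohort(cfg)
        res = EstrusBehaviorHMM(trajs[:4] + trajs[8:12], gmm_grid=[1, 2], seed=0).fit()
        path = tmp_path / "model.json"
        res.save(path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.transition.T, res.params.transition.T)
        for a, b in zip(loaded.emissions, res.params.emissions):
            np.testing.assert_array_equal(a.means, b.means)
            np.testing.assert_array_equal(a.variances, b.variances)
            np.testing.assert_array_equal(a.weights, b.weights)
        # decoding through the reloaded model is identical
        from capritrack.hmm import HMMResults

        dec1 = res.decode(trajs[4])
        dec2 = HMMResults.from_file(path).decode(trajs[4])
        np.testing.assert_array_equal(dec1, dec2)

    def test_summary_mentions_all_states(self):
        cfg = recovery_config(seed=7, n_frames=120)
        trajs, _ = simulate_cohort(cfg)
        res = EstrusBehaviorHMM(trajs[:2], gmm_grid=[1], seed=0).fit()
        text = res.summary()
        for word in ("approaching", "standing", "Transition"):
            assert word in text

    def test_unlabeled_training_data_rejected(self, rng):
        from capritrack.io import Trajectory

        t = Trajectory("u", False, x=rng.normal(size=10), y=rng.normal(size=10))
        with pytest.raises(ValueError):
            EstrusBehaviorHMM([t])
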