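"""Factor-graph emotion prediction: features, factors, inference, learning."""

import numpy as np
import pytest

from emotrain.series import EmotionSeries
from emotrain.enfg import (
    EnFGClassifier, FeatureVocabulary, activity_level, build_modality_features,
    factor_edges_from_network, predict_final,
)
from emotrain.experiments import (
    _random_model, sample_assignments, gradient_check, make_copying_cohort,
)
from emotrain.synthetic import SyntheticConfig, generate_community


class TestModalityFeatures:
    def test_two_positive_bins_encoding(self):
        """States [+1, +1] over two bins: unigrams at t-1 and t0, one bigram."""
        s = EmotionSeries("u", [1, 1], n_posts=[1, 1])
        feats = build_modality_features(s, [0, 1], mean_posts=1.0)
        assert ("emo", -1, "POS") in feats
        assert ("emo", 0, "POS") in feats
        assert ("emo2", 0, ("POS", "POS")) in feats
        assert ("bias",) in feats

    def test_activity_threshold_boundaries(self):
        """Exactly 1x the mean is medium (closed left), 2x is high."""
        assert activity_level(0.9, 1.0) == "low"
        assert activity_level(1.0, 1.0) == "medium"
        assert activity_level(1.9999, 1.0) == "medium"
        assert activity_level(2.0, 1.0) == "high"

    def test_mean_posting_gives_all_medium(self):
        s = EmotionSeries("u", [0, 0, 0], n_posts=[2, 2, 2])
        feats = build_modality_features(s, [0, 1, 2], mean_posts=2.0)
        acts = {f for f in feats if f[0] == "act"}
        assert acts == {("act", r, "medium") for r in (-2, -1, 0)}

    def test_empty_history_keeps_only_bias(self):
        s = EmotionSeries("u", [1, 0], n_posts=[1, 1])
        assert build_modality_features(s, [], 1.0) == {("bias",)}

    def test_missing_bins_break_bigrams(self):
        s = EmotionSeries("u", [1, np.nan, -1], n_posts=[1, 0, 1])
        feats = build_modality_features(s, [0, 1, 2], mean_posts=1.0)
        assert ("emo", 0, "NEG") in feats
        assert not any(f[0] == "emo2" for f in feats)

    def test_vocabulary_is_stable_across_encodes(self):
        vocab = FeatureVocabulary()
        a = vocab.encode([{("bias",), ("emo", 0, "POS")}])
        b = vocab.encode([{("bias",)}], grow=False)
        assert a.shape[1] == 2 and b.shape[1] == 2
        assert b[0].sum() == 1.0


class TestFactors:
    def _fitted(self, n_feat=2, alpha=None, beta=0.0, gamma=0.0, variant="coupled"):
        m = EnFGClassifier(variant=variant)
        m.alpha_ = np.zeros((n_feat, 3)) if alpha is None else np.asarray(alpha, float)
        m.beta_, m.gamma_ = float(beta), float(gamma)
        m.classes_ = np.array([-1, 0, 1])
        return m

    def test_zero_weights_give_uniform_distribution(self):
        m = self._fitted()
        x = np.ones((3, 2))
        assert m.eval_score(x, [1, 0, -1]) == 0.0
        np.testing.assert_allclose(m.infer_marginals(x), 1 / 3, atol=1e-12)

    def test_single_feature_log_odds(self):
        """One active modality feature with weight 1.5 on POS shifts the
        log-odds between matching and non-matching states by exactly 1.5."""
        alpha = np.zeros((1, 3))
        alpha[0, 2] = 1.5  # POS column
        m = self._fitted(n_feat=1, alpha=alpha)
        x = np.ones((1, 1))
        s_pos = m.eval_score(x, [1])
        s_neu = m.eval_score(x, [0])
        assert s_pos - s_neu == pytest.approx(1.5)
        marg = m.infer_marginals(x)[0]
        assert np.log(marg[2] / marg[1]) == pytest.approx(1.5, abs=1e-9)

    def test_literal_pairwise_factor_is_label_independent(self):
        """As printed, a Dual edge (g=2, gamma=0.7) adds 1.4 to every
        assignment and cancels in the marginals."""
        m = self._fitted(beta=0.0, gamma=0.7, variant="literal")
        x = np.zeros((2, 2))
        edges = [(0, 1, 0.0, 2.0)]
        scores = {
            (a, b): m.eval_score(x, [a, b], edges)
            for a in (-1, 0, 1) for b in (-1, 0, 1)
        }
        assert all(v == pytest.approx(1.4) for v in scores.values())
        np.testing.assert_allclose(m.infer_marginals(x, edges), 1 / 3, atol=1e-12)

    def test_coupled_pairwise_factor_rewards_agreement(self):
        m = self._fitted(beta=1.0, gamma=0.5)
        x = np.zeros((2, 2))
        edges = [(0, 1, 1.0, 2.0)]  # weight 1*1 + 0.5*2 = 2
        agree = m.eval_score(x, [1, 1], edges)
        disagree = m.eval_score(x, [1, 0], edges)
        assert agree - disagree == pytest.approx(2.0)
        marg = m.infer_marginals(x, edges, clamped={0: 1})
        assert marg[1, 2] > 0.5  # neighbor pulled toward POS

    def test_unknown_label_rejected(self):
        m = self._fitted()
        with pytest.raises(ValueError):
            m.eval_score(np.ones((1, 2)), [2])


class TestInference:
    def test_partition_normalizes_scores(self, rng):
        """exp(score - log Z) sums to 1 over all assignments."""
        for variant in ("coupled", "literal"):
            model, x, edges = _random_model(rng, 5, alpha_sd=0.8, w_sd=0.5,
                                            variant=variant)
            log_z = model.log_partition(x, edges)
            total = sum(
                np.exp(model.eval_score(x, [a - 1 for a in assign], edges) - log_z)
                for assign in np.ndindex(3, 3, 3, 3, 3)
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_marginals_normalize(self, rng):
        model, x, edges = _random_model(rng, 7)
        for threshold in (12, 0):  # enumeration, then loopy
            model.enum_threshold = threshold
            marg = model.infer_marginals(x, edges)
            np.testing.assert_allclose(marg.sum(axis=1), 1.0, atol=1e-9)

    def test_tree_message_passing_matches_enumeration(self, rng):
        model, x, _ = _random_model(rng, 6, alpha_sd=0.5, w_sd=0.4, bp_tol=1e-12)
        chain = [(i, i + 1, 1.0, float(i % 3)) for i in range(5)]
        model.enum_threshold = 12
        exact = model.infer_marginals(x, chain)
        model.enum_threshold = 0
        bp = model.infer_marginals(x, chain)
        np.testing.assert_allclose(bp, exact, atol=1e-9)

    def test_loopy_close_to_enumeration_on_small_graphs(self, rng):
        worst = 0.0
        for _ in range(10):
            model, x, edges = _random_model(rng, 8, bp_tol=1e-12)
            model.enum_threshold = 12
            exact = model.infer_marginals(x, edges)
            model.enum_threshold = 0
            loopy = model.infer_marginals(x, edges)
            worst = max(worst, 0.5 * np.abs(exact - loopy).sum(axis=1).max())
        assert worst <= 1e-3

    def test_clamping_restricts_support(self, rng):
        model, x, edges = _random_model(rng, 5)
        marg = model.infer_marginals(x, edges, clamped={2: -1})
        assert marg[2, 0] == pytest.approx(1.0, abs=1e-9)


class TestLearning:
    def test_gradient_matches_finite_differences(self):
        assert gradient_check(seed=0) < 1e-5

    def test_single_node_reduces_to_multinomial_logistic(self, rng):
        """With one node the model is a multinomial logistic regression;
        at lam -> 0 the fitted marginal matches empirical frequencies."""
        x = np.ones((1, 1))
        y = rng.choice([-1, 0, 1], size=(600, 1), p=[0.5, 0.3, 0.2])
        m = EnFGClassifier(lam=1e-8, gtol=1e-8).fit(x, y)
        marg = m.infer_marginals(x)[0]
        freq = [(y == c).mean() for c in (-1, 0, 1)]
        np.testing.assert_allclose(marg, freq, atol=0.01)

    def test_strong_regularization_kills_weights(self, rng):
        model, x, edges = _random_model(rng, 4)
        y = sample_assignments(model, x, edges, 50, rng)
        m = EnFGClassifier(lam=1e6).fit(x, y, edges)
        assert np.abs(m.alpha_).max() < 1e-3
        assert abs(m.beta_) < 1e-3 and abs(m.gamma_) < 1e-3

    def test_fitted_parameters_beat_perturbations_on_held_out(self, rng):
        """Data generated from known weights: the fitted model dominates
        +-0.5 coordinate perturbations of itself in held-out likelihood."""
        gen, x, edges = _random_model(rng, 5, n_feat=2, edge_p=0.6,
                                      alpha_sd=0.8, w_sd=0.5)
        train = sample_assignments(gen, x, edges, 800, rng)
        held = [(x, row) for row in sample_assignments(gen, x, edges, 400, rng)]
        m = EnFGClassifier(lam=0.01).fit(x, train, edges)
        ll_fit = m.log_likelihood(held, edges)
        theta = m._pack(m.alpha_, m.beta_, m.gamma_)
        for _ in range(5):
            signs = rng.choice([-0.5, 0.5], size=theta.size)
            pert = EnFGClassifier()
            pert.alpha_, pert.beta_, pert.gamma_ = m._unpack(theta + signs, 2)
            pert.classes_ = np.array([-1, 0, 1])
            assert ll_fit >= pert.log_likelihood(held, edges)

    def test_informative_entrainment_factors_lift_training_likelihood(self, rng):
        """Adding pairwise factors that encode real agreement structure never
        reduces the training log-likelihood."""
        gen, x, edges = _random_model(rng, 4, w_sd=0.0)
        gen.beta_, gen.gamma_ = 0.8, 0.4  # planted agreement signal
        y = sample_assignments(gen, x, edges, 500, rng)
        with_edges = EnFGClassifier(lam=0.01).fit(x, y, edges)
        without = EnFGClassifier(lam=0.01).fit(x, y, edges=None)
        inst = [(x, row) for row in y]
        assert with_edges.log_likelihood(inst, edges) >= without.log_likelihood(inst, None) - 1e-9


class TestPredictFinal:
    def test_deterministic_self_copy_reaches_perfect_accuracy(self):
        """A cohort whose state never changes is perfectly predictable from
        its own unigram history."""
        series = {
            u: EmotionSeries(u, np.full(20, float(s)))
            for u, s in enumerate([-1, -1, 0, 0, 1, 1, 1, -1])
        }
        res = predict_final(series, folds=4, history_len=2,
                            use_entrainment=False, seed=0)
        assert res.accuracy == 1.0

    def test_shuffled_labels_stay_near_chance(self):
        """With iid uniform states and no coupling, accuracy sits near 1/3."""
        rng = np.random.default_rng(0)
        accs = []
        for rep in range(6):
            series = {
                u: EmotionSeries(u, rng.integers(-1, 2, 40).astype(float))
                for u in range(8)
            }
            res = predict_final(series, folds=4, history_len=2,
                                use_entrainment=False, seed=rep)
            accs.append(res.accuracy)
        se = np.sqrt((1 / 3) * (2 / 3) / (8 * len(accs)))
        assert abs(np.mean(accs) - 1 / 3) < 3 * se + 0.05

    def test_entrainment_factors_beat_modality_only_on_copying_cohort(self):
        from emotrain.experiments import ablation_direction

        out = ablation_direction(n_pairs=3, n_steps=400, copy_p=0.95, n_reps=2, seed=0)
        assert out["accuracy_entrainment"] >= out["accuracy_modality_only"]

    def test_final_bin_never_enters_features(self):
        """Changing the final-bin states must not change the training
        instances or the factor edges (only the gold labels)."""
        series = make_copying_cohort(n_pairs=2, n_steps=30, seed=1)
        res_a = predict_final(series, folds=2, use_entrainment=False, seed=0)
        flipped = {
            u: EmotionSeries(u, np.concatenate([s.states[:-1], [-s.states[-1] if s.states[-1] else 1.0]]))
            for u, s in series.items()
        }
        res_b = predict_final(flipped, folds=2, use_entrainment=False, seed=0)
        assert res_a.predictions == res_b.predictions
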