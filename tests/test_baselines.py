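import numpy as np
import pytest

from deepgam import (
    Dataset,
    FeatureRanking,
    RankingError,
    TrainingConfig,
    hinge_loss,
    init_model,
    logistic_loss,
    rank_by_gate,
    rank_by_l1,
    select_and_retrain,
    train,
    train_linear,
    train_mlp,
)


def _separable(rng, n=200, m=2):
    """Linearly separable toy with a 0.2 margin around the boundary."""
    X = rng.standard_normal((n, m))
    X[:, 0] += np.where(X[:, 0] > 0, 0.1, -0.1)
    y = np.where(X[:, 0] > 0, 1.0, -1.0)
    return Dataset(X, y, tuple(f"f{i}" for i in range(m)))


class TestLossValues:
    def test_hinge_zero_when_margin_met(self):
        assert hinge_loss(np.array([1.0]), np.array([1.0])) == 0.0
        assert hinge_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(0.5)

    def test_logistic_log2_at_zero_score(self):
        assert logistic_loss(np.array([0.0]), np.array([1.0])) == pytest.approx(np.log(2))

    @pytest.mark.parametrize("loss_kind", ["hinge", "cross-entropy"])
    def test_gradients_match_finite_differences(self, loss_kind, rng):
        lossf = hinge_loss if loss_kind == "hinge" else logistic_loss
        for _ in range(100):
            w = rng.standard_normal(3)
            X = rng.standard_normal((5, 3))
            y = np.where(rng.random(5) > 0.5, 1.0, -1.0)
            s = X @ w
            if loss_kind == "hinge" and np.any(np.abs(1 - y * s) < 1e-3):
                continue  # skip the kink
            if loss_kind == "hinge":
                dscore = np.where((1 - y * s) > 0, -y, 0.0) / 5
            else:
                dscore = -y / (1 + np.exp(y * s)) / 5
            grad = X.T @ dscore
            eps = 1e-5
            for j in range(3):
                w[j] += eps
                up = lossf(X @ w, y)
                w[j] -= 2 * eps
                dn = lossf(X @ w, y)
                w[j] += eps
                assert grad[j] == pytest.approx((up - dn) / (2 * eps), abs=1e-5)


class TestLinearHeads:
    @pytest.mark.parametrize("loss_kind", ["hinge", "cross-entropy"])
    def test_separable_toy_perfect_heldout(self, loss_kind, rng):
        train_d = _separable(rng, 300)
        test_d = _separable(rng, 100)
        cfg = TrainingConfig(epochs=20, seed=0)
        head = train_linear(train_d, cfg, loss_kind)
        assert (head.classify(test_d.X) == test_d.y).mean() == 1.0

    def test_deterministic(self, rng):
        d = _separable(rng)
        cfg = TrainingConfig(epochs=5, seed=1)
        h1 = train_linear(d, cfg, "hinge")
        h2 = train_linear(d, cfg, "hinge")
        np.testing.assert_array_equal(h1.weights, h2.weights)


class TestMLP:
    def test_xor_pattern_needs_nonlinearity(self, rng):
        n = 400
        X = rng.standard_normal((n, 2))
        y = np.where(X[:, 0] * X[:, 1] > 0, 1.0, -1.0)
        d = Dataset(X, y, ("a", "b"))
        Xt = rng.standard_normal((200, 2))
        test = Dataset(Xt, np.where(Xt[:, 0] * Xt[:, 1] > 0, 1.0, -1.0), ("a", "b"))
        cfg = TrainingConfig(epochs=40, seed=0)
        mlp = train_mlp(d, cfg, hidden=32)
        acc = (mlp.classify(test.X) == test.y).mean()
        assert acc > 0.9

    def test_scores_map_probabilities_to_unit_interval(self, rng):
        d = _separable(rng)
        mlp = train_mlp(d, TrainingConfig(epochs=3, seed=0), hidden=8)
        p = mlp.predict_proba(d.X)
        assert (p >= 0).all() and (p <= 1).all()
        np.testing.assert_allclose(mlp.predict_score(d.X), 2 * p - 1)

    def test_deterministic(self, rng):
        d = _separable(rng)
        m1 = train_mlp(d, TrainingConfig(epochs=3, seed=5), hidden=8)
        m2 = train_mlp(d, TrainingConfig(epochs=3, seed=5), hidden=8)
        np.testing.assert_array_equal(m1.W1, m2.W1)


class TestRankByGate:
    def test_order_and_tie_rule(self):
        m = init_model(M=3, C=2, seed=0)
        m.phi = np.array([0.2, -0.5, 0.9])
        r = rank_by_gate(m)
        assert r.indices == (2, 0, 1)
        m.phi = np.array([0.3, 0.3, 0.1])
        assert rank_by_gate(m).indices == (0, 1, 2)  # tie -> lower index first

    def test_scores_non_increasing(self):
        m = init_model(M=5, C=2, seed=0)
        m.phi = np.array([0.1, -0.2, 0.4, 0.0, -0.1])
        r = rank_by_gate(m)
        assert all(a >= b for a, b in zip(r.scores, r.scores[1:]))
        # alive features precede dead ones
        alive_ranks = [r.indices.index(j) for j in (0, 2, 3)]
        dead_ranks = [r.indices.index(j) for j in (1, 4)]
        assert max(alive_ranks) < min(dead_ranks)


class TestRankByL1:
    def _linear_data(self, rng, n=200, m=10):
        X = rng.standard_normal((n, m))
        y = np.where(X[:, 0] + 0.3 * rng.standard_normal(n) > 0, 1.0, -1.0)
        return Dataset(X, y, tuple(f"f{i}" for i in range(m)))

    def test_dominant_feature_ranked_first(self, rng):
        d = self._linear_data(rng)
        r = rank_by_l1(d, regularization_strength=0.05)
        assert r.indices[0] == 0

    def test_huge_strength_error_path(self, rng):
        d = self._linear_data(rng)
        with pytest.raises(RankingError, match="smaller"):
            rank_by_l1(d, regularization_strength=1e6)

    def test_zero_strength_reduces_to_least_squares(self, rng):
        d = self._linear_data(rng, n=100, m=4)
        r = rank_by_l1(d, regularization_strength=0.0)
        coef = np.linalg.lstsq(np.c_[d.X, np.ones(d.n)], d.y, rcond=None)[0][:-1]
        expect = tuple(int(i) for i in np.argsort(-np.abs(coef), kind="stable"))
        assert r.indices == expect

    def test_agrees_with_sklearn_lasso(self, rng):
        from sklearn.linear_model import Lasso

        d = self._linear_data(rng, n=150, m=6)
        alpha = 0.03
        ours = rank_by_l1(d, regularization_strength=alpha)
        sk = Lasso(alpha=alpha, fit_intercept=True, tol=1e-12, max_iter=50_000).fit(d.X, d.y)
        order_sk = tuple(int(i) for i in np.argsort(-np.abs(sk.coef_), kind="stable"))
        assert ours.indices[:3] == order_sk[:3]
        # coefficient values agree closely
        coef_ours = np.zeros(6)
        for i, s in zip(ours.indices, ours.scores):
            coef_ours[i] = s
        np.testing.assert_allclose(coef_ours, np.abs(sk.coef_), atol=1e-4)

    def test_bisection_targets_k_nonzero(self, rng):
        d = self._linear_data(rng, n=200, m=10)
        r = rank_by_l1(d, k=3)
        assert sum(s > 0 for s in r.scores) >= 3


class TestSelectAndRetrain:
    def test_k_zero_and_too_large_rejected(self, rng):
        d = _separable(rng, m=4)
        ranking = FeatureRanking(indices=(0, 1, 2, 3), scores=(4.0, 3.0, 2.0, 1.0), method="x")
        cfg = TrainingConfig(epochs=1, channels=4, seed=0)
        with pytest.raises(RankingError):
            select_and_retrain(d, ranking, 0, cfg)
        with pytest.raises(RankingError):
            select_and_retrain(d, ranking, 9, cfg)

    def test_full_feature_retrain_equals_frozen_run(self, rng):
        d = _separable(rng, n=100, m=3)
        ranking = FeatureRanking(indices=(0, 1, 2), scores=(3.0, 2.0, 1.0), method="x")
        cfg = TrainingConfig(epochs=3, channels=8, seed=4)
        m_sel, cols = select_and_retrain(d, ranking, 3, cfg)
        frozen_cfg = cfg.replace(freeze_gates=True, lambda2=0.0)
        m_ref, _ = train(init_model(3, C=8, phi_init=0.05, seed=4,
                                    feature_names=d.feature_names), d, frozen_cfg)
        np.testing.assert_array_equal(m_sel.predict_score(d.X), m_ref.predict_score(d.X))

    def test_retrained_subset_model_works(self, rng):
        d = _separable(rng, n=200, m=5)
        ranking = FeatureRanking(indices=(0, 1, 2, 3, 4), scores=(5.0, 4.0, 3.0, 2.0, 1.0), method="x")
        cfg = TrainingConfig(epochs=10, channels=16, seed=0)
        model, cols = select_and_retrain(d, ranking, 2, cfg)
        assert cols == (0, 1)
        acc = (model.classify(d.subset_columns(cols).X) == d.y).mean()
        assert acc > 0.9

    @pytest.mark.parametrize("head", ["svm", "logistic", "mlp"])
    def test_baseline_heads_supported(self, head, rng):
        d = _separable(rng, n=120, m=4)
        ranking = FeatureRanking(indices=(0, 1, 2, 3), scores=(4.0, 3.0, 2.0, 1.0), method="x")
        cfg = TrainingConfig(epochs=3, channels=8, seed=0)
        model, cols = select_and_retrain(d, ranking, 2, cfg, head=head)
        assert model.predict_score(d.subset_columns(cols).X).shape == (d.n,)
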