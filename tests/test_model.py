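import numpy as np
import pytest

from ldapred.features import build_pair_set
from ldapred.model import (
    DualCNNModel,
    ModelConfig,
    channel_forward,
    fuse_scores,
    loss,
    predict_disease,
    predict_pairs,
    train,
)
from ldapred.propagation import PropagationConfig, propagate_network


def mini_model(width=6, seed=3, **kw):
    cfg = ModelConfig(nconv1=1, nconv2=1, nconv3=1, nconv4=1, seed=seed, **kw)
    return DualCNNModel(cfg, input_width=width), cfg


def randomize_params(model, seed=0, scale=0.5):
    """Move all parameters (incl. biases) away from ReLU kinks."""
    rng = np.random.default_rng(seed)
    for ch in (model.left, model.right):
        for k in ch.params:
            ch.params[k] = rng.normal(size=ch.params[k].shape) * scale


class TestChannelForward:
    def test_hand_computed_single_filter(self):
        """Pencil-and-paper trace of conv-pool-conv-pool-dense on a 2x2 input.

        With identity-diagonal first filter, all-ones second filter and
        dense weights (+1, -1): padded input -> conv picks up a+d in the
        centre; the single pool window keeps max(1,2,3,5)=5; second conv
        sums the padded 3x3 single-entry map back to 5 everywhere it
        covers it; final scores are (5, -5).
        """
        model, _ = mini_model(width=2)
        ch = model.left
        ch.params["W1"] = np.array([[[[1.0, 0.0], [0.0, 1.0]]]])
        ch.params["b1"] = np.zeros(1)
        ch.params["W2"] = np.ones((1, 1, 2, 2))
        ch.params["b2"] = np.zeros(1)
        ch.params["Wd"] = np.array([[1.0], [-1.0]])
        ch.params["bd"] = np.zeros(2)
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(channel_forward(ch, X), [5.0, -5.0])

    def test_zero_input_zero_bias_gives_zero_scores(self):
        model, _ = mini_model(width=8)
        np.testing.assert_allclose(channel_forward(model.left, np.zeros((2, 8))), [0.0, 0.0])

    def test_deterministic_across_runs(self):
        X = np.random.default_rng(1).normal(size=(2, 10))
        m1, _ = mini_model(width=10, seed=5)
        m2, _ = mini_model(width=10, seed=5)
        np.testing.assert_array_equal(channel_forward(m1.left, X), channel_forward(m2.left, X))

    def test_width_mismatch_rejected(self):
        model, _ = mini_model(width=6)
        with pytest.raises(ValueError, match="shape"):
            channel_forward(model.left, np.zeros((2, 7)))

    def test_depends_only_on_feature_values(self):
        """Identical feature matrices score identically regardless of provenance."""
        model, _ = mini_model(width=6)
        X = np.random.default_rng(2).normal(size=(2, 6))
        np.testing.assert_array_equal(channel_forward(model.left, X), channel_forward(model.left, X.copy()))


class TestFuseScores:
    def test_lambda_one_is_left_probability(self):
        s1, s2 = np.array([0.3, 1.2]), np.array([-2.0, 0.5])
        p1 = np.exp(1.2) / (np.exp(0.3) + np.exp(1.2))
        assert fuse_scores(s1, s2, 1.0) == pytest.approx(p1)

    def test_endpoint_arithmetic_with_default_lambda(self):
        # p1 ~ 1, p2 ~ 0 at extreme raw scores -> fused ~ lambda
        s1 = np.array([-40.0, 40.0])
        s2 = np.array([40.0, -40.0])
        assert fuse_scores(s1, s2, 0.7) == pytest.approx(0.7, abs=1e-12)

    def test_equal_probabilities_fixed_point(self):
        s = np.array([0.1, 0.4])
        p = np.exp(0.4) / (np.exp(0.1) + np.exp(0.4))
        assert fuse_scores(s, s, 0.5) == pytest.approx(p)

    def test_monotone_in_each_channel(self):
        base = np.array([0.0, 0.0])
        better = np.array([0.0, 1.0])
        assert fuse_scores(better, base, 0.4) > fuse_scores(base, base, 0.4)
        assert fuse_scores(base, better, 0.4) > fuse_scores(base, base, 0.4)


class TestLoss:
    def test_even_scores_give_ln2(self):
        for label in (0, 1):
            l1, l2 = loss(np.zeros(2), np.zeros(2), label)
            assert l1 == pytest.approx(np.log(2))
            assert l2 == pytest.approx(np.log(2))

    def test_confident_correct_loss_vanishes(self):
        s = np.array([-50.0, 50.0])  # p(assoc) -> 1
        l1, _ = loss(s, s, 1)
        assert l1 == pytest.approx(0.0, abs=1e-12)

    def test_batch_loss_is_mean_of_per_pair_losses(self):
        model, _ = mini_model(width=6)
        randomize_params(model)
        rng = np.random.default_rng(7)
        S, T = rng.normal(size=(3, 2, 6)), rng.normal(size=(3, 2, 6))
        y = np.array([1, 0, 1])
        total = model.batch_loss(S, T, y)
        per_pair = [
            sum(loss(model.left.forward(S[k][None])[0], model.right.forward(T[k][None])[0], int(y[k])))
            for k in range(3)
        ]
        assert total == pytest.approx(np.mean(per_pair))

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            loss(np.zeros(2), np.zeros(2), 2)


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        model, _ = mini_model(width=6)
        randomize_params(model, seed=0)
        rng = np.random.default_rng(1)
        S, T = rng.normal(size=(3, 2, 6)), rng.normal(size=(3, 2, 6))
        y = np.array([1, 0, 1])
        _, grads = model._batch_loss_and_grads(S, T, y)
        for name, ch in (("left", model.left), ("right", model.right)):
            for k, p in ch.params.items():
                num = np.zeros_like(p)
                it = np.nditer(p, flags=["multi_index"])
                for _ in it:
                    ix = it.multi_index
                    orig = p[ix]
                    p[ix] = orig + 1e-5
                    lp = model.batch_loss(S, T, y)
                    p[ix] = orig - 1e-5
                    lm = model.batch_loss(S, T, y)
                    p[ix] = orig
                    num[ix] = (lp - lm) / 2e-5
                denom = max(np.abs(num).max(), np.abs(grads[name][k]).max(), 1e-8)
                rel = np.abs(num - grads[name][k]).max() / denom
                assert rel < 1e-4, f"{name}.{k}: rel grad error {rel:.2e}"


def separable_training_set(toy_net, n=20):
    """Synthetic linearly separable features: positives have large entries."""
    rng = np.random.default_rng(0)
    W = 9
    S = rng.normal(size=(n, 2, W)) * 0.1
    T = rng.normal(size=(n, 2, W)) * 0.1
    y = np.array([1, 0] * (n // 2))
    S[y == 1] += 2.0
    T[y == 1] += 2.0
    from ldapred.features import LabeledPairSet

    # pairs are bookkeeping only here; features are supplied directly
    pairs = [(k // 4, k % 4) for k in range(n)]
    return LabeledPairSet(pairs=pairs, labels=y, S=S, T=T)


class TestTraining:
    def test_overfits_separable_pairs(self, toy_net):
        ts = separable_training_set(toy_net)
        cfg = ModelConfig(nconv1=2, nconv2=2, nconv3=2, nconv4=2, epochs=200,
                          learning_rate=5e-3, batch_size=10, seed=1)
        model = DualCNNModel(cfg, input_width=9)
        initial = model.batch_loss(ts.S, ts.T, ts.labels)
        train(model, ts, cfg)
        final = model.batch_loss(ts.S, ts.T, ts.labels)
        assert final < 0.1 * initial

    def test_same_seed_identical_parameters(self, toy_net):
        ts = separable_training_set(toy_net)
        cfg = ModelConfig(nconv1=1, nconv2=1, nconv3=1, nconv4=1, epochs=5, seed=9)
        finals = []
        for _ in range(2):
            model = DualCNNModel(cfg, input_width=9)
            train(model, ts, cfg)
            finals.append({f"{n}.{k}": ch.params[k].copy()
                           for n, ch in (("l", model.left), ("r", model.right)) for k in ch.params})
        for k in finals[0]:
            np.testing.assert_array_equal(finals[0][k], finals[1][k])

    def test_lambda_does_not_enter_training(self, toy_net):
        """Fusion weight is inference-only: training is invariant to it."""
        ts = separable_training_set(toy_net)
        params = []
        for lam in (0.1, 0.9):
            cfg = ModelConfig(nconv1=1, nconv2=1, nconv3=1, nconv4=1, epochs=5,
                              seed=9, lambda_weight=lam)
            model = DualCNNModel(cfg, input_width=9)
            train(model, ts, cfg)
            params.append(np.concatenate([ch.params[k].ravel()
                                          for ch in (model.left, model.right) for k in sorted(ch.params)]))
        np.testing.assert_array_equal(params[0], params[1])

    def test_single_class_rejected(self, toy_net):
        ts = separable_training_set(toy_net)
        from ldapred.features import LabeledPairSet

        ones = LabeledPairSet(pairs=ts.pairs, labels=np.ones_like(ts.labels), S=ts.S, T=ts.T)
        model, cfg = mini_model(width=9)
        with pytest.raises(ValueError, match="both classes"):
            train(model, ones, cfg)


class TestPrediction:
    def test_untrained_model_rejected(self, toy_net):
        pn = propagate_network(toy_net, PropagationConfig())
        model, _ = mini_model(width=9)
        with pytest.raises(RuntimeError, match="not been trained"):
            predict_disease(model, toy_net, pn, 0)

    def test_scores_shape_and_range(self, toy_net):
        pn = propagate_network(toy_net, PropagationConfig())
        pos = [tuple(p) for p in np.argwhere(toy_net.A == 1)]
        neg = [tuple(p) for p in np.argwhere(toy_net.A == 0)]
        ts = build_pair_set(toy_net, pn, pos + neg, [1] * len(pos) + [0] * len(neg))
        model, cfg = mini_model(width=9, epochs=3)
        train(model, ts, cfg)
        scores = predict_disease(model, toy_net, pn, 1)
        assert scores.shape == (toy_net.nl,)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_planted_positives_score_above_noise(self, small_synthetic):
        """After training, planted associations outrank non-associations."""
        spec, net, planted = small_synthetic
        pn = propagate_network(net, PropagationConfig())
        pos = [tuple(p) for p in np.argwhere(net.A == 1)]
        neg = [tuple(p) for p in np.argwhere(net.A == 0)]
        ts = build_pair_set(net, pn, pos + neg, [1] * len(pos) + [0] * len(neg))
        cfg = ModelConfig(epochs=40, seed=2)
        model = DualCNNModel(cfg, input_width=net.nl + net.nd + net.nm)
        train(model, ts, cfg)
        pos_scores = predict_pairs(model, net, pn, pos)
        neg_scores = predict_pairs(model, net, pn, neg)
        assert pos_scores.mean() > neg_scores.mean() + 0.1
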