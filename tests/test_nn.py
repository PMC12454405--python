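"""Attention contracts, gradient correctness, and the CLA forward trace."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ricelai.models import CLAConfig, CLANet
from ricelai.nn import attention_context, attention_normalize, attention_scores


class TestAttentionOps:
    def test_zero_projection_vector_gives_zero_scores(self, rng):
        h = rng.normal(size=(5, 3))
        e = attention_scores(h, np.zeros(2), U=rng.normal(size=(3, 4)),
                             W=rng.normal(size=(2, 4)), v=np.zeros(4))
        np.testing.assert_array_equal(e, np.zeros(5))

    def test_scalar_hand_evaluation(self):
        # h=(1), s=0, U=1, W=0, v=2 -> 2*tanh(1)
        e = attention_scores(np.array([[1.0]]), np.array([0.0]),
                             U=np.array([[1.0]]), W=np.array([[0.0]]), v=np.array([2.0]))
        assert e[0] == pytest.approx(2 * math.tanh(1), abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_scores(rng.normal(size=(5, 3)), np.zeros(2),
                             U=rng.normal(size=(4, 4)), W=rng.normal(size=(2, 4)),
                             v=rng.normal(size=4))

    def test_uniform_softmax(self):
        np.testing.assert_allclose(attention_normalize(np.zeros(4)), np.full(4, 0.25))

    def test_hand_softmax(self):
        w = attention_normalize(np.array([math.log(2), 0.0]))
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)

    def test_single_unmasked_step_takes_all_weight(self):
        w = attention_normalize(np.array([5.0, -1.0, 2.0]),
                                mask=np.array([False, True, False]))
        np.testing.assert_allclose(w, [0.0, 1.0, 0.0])

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            attention_normalize(np.zeros(3), mask=np.zeros(3, dtype=bool))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_weights_nonnegative_sum_to_one_shift_invariant(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(1, 12))
        scores = rng.normal(scale=5, size=T)
        mask = rng.random(T) < 0.7
        if not mask.any():
            mask[rng.integers(T)] = True
        w = attention_normalize(scores, mask)
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(w[~mask] == 0)
        w_shift = attention_normalize(scores + 3.7, mask)
        np.testing.assert_allclose(w, w_shift, atol=1e-9)

    def test_one_hot_weights_select_state(self, rng):
        h = rng.normal(size=(4, 3))
        w = np.array([0.0, 0.0, 1.0, 0.0])
        np.testing.assert_array_equal(attention_context(h, w), h[2])

    def test_uniform_weights_give_mean(self, rng):
        h = rng.normal(size=(4, 3))
        np.testing.assert_allclose(attention_context(h, np.full(4, 0.25)), h.mean(axis=0))

    def test_hand_weighted_sum(self):
        h = np.array([[0.0, 3.0], [3.0, 0.0]])
        np.testing.assert_allclose(attention_context(h, np.array([2 / 3, 1 / 3])), [1.0, 2.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_context_is_convex_combination(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.normal(size=(6, 4))
        w = attention_normalize(rng.normal(size=6))
        ctx = attention_context(h, w)
        brute = sum(w[i] * h[i] for i in range(6))
        np.testing.assert_allclose(ctx, brute, atol=1e-12)
        assert np.all(ctx >= h.min(axis=0) - 1e-12)
        assert np.all(ctx <= h.max(axis=0) + 1e-12)


TINY = CLAConfig(conv_filters=1, conv_kernel=3, pool_size=2, lstm_units=2,
                 attention_dim=2, head_units=2, dropout_rate=0.0, seed=3)


def _trace_cla(net, X, mask):
    """Independent straight-line re-implementation of the CLA forward pass.

    Plain loops over the documented recurrences: mask-channel append, same-
    padded conv over time, ReLU, max pool, LSTM gate equations, additive
    attention with learned query, dense head.
    """
    B, T, F = X.shape
    Xa = np.concatenate([X, mask[:, :, None].astype(float)], axis=2)
    Wc, bc = net.conv.params["W"], net.conv.params["b"]
    k = Wc.shape[0]
    C = Wc.shape[2]
    left = (k - 1) // 2
    preds = []
    for b in range(B):
        # conv + relu
        conv = np.zeros((T, C))
        for t in range(T):
            acc = bc.copy()
            for j in range(k):
                src = t + j - left
                if 0 <= src < T:
                    acc = acc + Xa[b, src] @ Wc[j]
            conv[t] = np.maximum(acc, 0.0)
        # max pool (pad with -inf)
        p = net.pool.pool
        Tp = math.ceil(T / p)
        pooled = np.full((Tp, C), -np.inf)
        pmask = np.zeros(Tp, dtype=bool)
        for t2 in range(Tp):
            for j in range(p):
                src = t2 * p + j
                if src < T:
                    pooled[t2] = np.maximum(pooled[t2], conv[src])
                    pmask[t2] |= mask[b, src]
        # lstm
        H = net.lstm.H
        Wx, Wh, bl = net.lstm.params["Wx"], net.lstm.params["Wh"], net.lstm.params["b"]
        h = np.zeros(H)
        c = np.zeros(H)
        states = []
        for t2 in range(Tp):
            pre = pooled[t2] @ Wx + h @ Wh + bl
            i = 1 / (1 + np.exp(-pre[:H]))
            f = 1 / (1 + np.exp(-pre[H:2 * H]))
            g = np.tanh(pre[2 * H:3 * H])
            o = 1 / (1 + np.exp(-pre[3 * H:]))
            c = f * c + i * g
            h = o * np.tanh(c)
            states.append(h)
        # additive attention with learned query
        U, Wq, s, v = (net.attn.params[key] for key in ("U", "W", "s", "v"))
        scores = [float(v @ np.tanh(U.T @ st_ + Wq.T @ s)) for st_ in states]
        scores = [sc if pm else -1e30 for sc, pm in zip(scores, pmask)]
        m = max(scores)
        exps = [math.exp(sc - m) for sc in scores]
        alphas = [e / sum(exps) for e in exps]
        ctx = sum(a * st_ for a, st_ in zip(alphas, states))
        # head
        W1, b1 = net.head.fc1.params["W"], net.head.fc1.params["b"]
        W2, b2 = net.head.fc2.params["W"], net.head.fc2.params["b"]
        hid = np.maximum(ctx @ W1 + b1, 0.0)
        preds.append(float((hid @ W2 + b2)[0]))
    return np.array(preds)


class TestCLAForward:
    def test_matches_independent_trace(self, rng):
        net = CLANet(2, TINY)
        # randomize all parameters so the check is not structure-trivial
        for layer in net.layers:
            for key, p in layer.params.items():
                layer.params[key] = rng.normal(scale=0.7, size=p.shape)
        X = rng.normal(size=(6, 4, 2))
        mask = np.ones((6, 4), dtype=bool)
        mask[0, :2] = False
        mask[3, :1] = False
        pred = net.predict(X, mask)
        expected = _trace_cla(net, X, mask)
        np.testing.assert_allclose(pred, expected, atol=1e-6)

    def test_zero_head_weights_give_bias(self, rng):
        net = CLANet(2, TINY)
        net.head.fc2.params["W"][:] = 0.0
        net.head.fc2.params["b"][:] = 1.25
        X = rng.normal(size=(3, 4, 2))
        mask = np.ones((3, 4), dtype=bool)
        np.testing.assert_allclose(net.predict(X, mask), 1.25)

    def test_inference_is_deterministic(self, rng):
        net = CLANet(2, TINY)
        X = rng.normal(size=(2, 4, 2))
        mask = np.ones((2, 4), dtype=bool)
        Xd = np.concatenate([X, X])
        md = np.concatenate([mask, mask])
        pred = net.predict(Xd, md)
        np.testing.assert_array_equal(pred[:2], pred[2:])

    def test_attention_weights_normalized_in_forward(self, rng):
        net = CLANet(2, TINY)
        X = rng.normal(size=(5, 4, 2))
        mask = np.ones((5, 4), dtype=bool)
        mask[1, :3] = False
        net.predict(X, mask)
        w = net.last_attention_weights
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_gradients_match_finite_differences(self, rng):
        cfg = CLAConfig(conv_filters=3, conv_kernel=3, pool_size=2, lstm_units=4,
                        attention_dim=3, head_units=3, dropout_rate=0.0, seed=7)
        net = CLANet(2, cfg)
        X = rng.normal(size=(5, 6, 2))
        mask = np.ones((5, 6), dtype=bool)
        mask[0, :2] = False
        y = rng.normal(size=5)

        def loss():
            p = net._forward(X, mask, None)
            return float(np.mean((p - y) ** 2))

        pred = net._forward(X, mask, None)
        for layer in net.layers:
            layer.zero_grad()
        net._backward(2 * (pred - y) / len(y))
        for layer in net.layers:
            for key, p in layer.params.items():
                g = layer.grads[key]
                flat_idx = rng.choice(p.size, size=min(4, p.size), replace=False)
                for fi in flat_idx:
                    idx = np.unravel_index(fi, p.shape)
                    eps = 1e-6
                    old = p[idx]
                    p[idx] = old + eps
                    lp = loss()
                    p[idx] = old - eps
                    lm = loss()
                    p[idx] = old
                    num = (lp - lm) / (2 * eps)
                    assert abs(num - g[idx]) < 1e-6 + 1e-3 * abs(num), (
                        f"{type(layer).__name__}.{key}{idx}"
                    )


class TestEarlyStopping:
    def test_halts_patience_epochs_after_best(self, rng, monkeypatch):
        net = CLANet(2, TINY)
        X = rng.normal(size=(12, 4, 2))
        mask = np.ones((12, 4), dtype=bool)
        y = rng.normal(size=12)
        calls = {"n": 0}

        def fake_val(self, *args):
            calls["n"] += 1
            return 1.0 / calls["n"] if calls["n"] <= 5 else 0.2  # best at epoch 5

        monkeypatch.setattr(type(net), "_val_loss", fake_val)
        history = net.fit(X, mask, y, X, mask, y, max_epochs=100, patience=10, seed=0)
        assert history["stopped_epoch"] == 15
        assert history["best_epoch"] == 5

    def test_training_reduces_loss(self, rng):
        net = CLANet(2, TINY)
        X = rng.normal(size=(24, 4, 2))
        mask = np.ones((24, 4), dtype=bool)
        y = X[:, -1, 0] * 2 + 1
        history = net.fit(X, mask, y, X, mask, y, max_epochs=60, patience=60,
                          seed=0, l2=0.0)
        best = history["best_epoch"] - 1
        assert history["train_loss"][best] <= history["train_loss"][0]
        assert history["val_loss"][best] < history["val_loss"][0]
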