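"""LSTM cell, attention, risk heads, checkpointing and the gradient oracle."""

import numpy as np
import pytest

from chrononet import _autodiff as ad
from chrononet.losses import (
    LossConfig,
    attention_entropy_term,
    bce_sequence,
    multitask_loss,
    smoothness_penalty,
    total_loss,
)
from chrononet.model import (
    ChronoNetParams,
    EncoderState,
    ModelConfig,
    UndefinedAttentionError,
    attention_weights,
    context_vector,
    encode_sequence,
    gradient_check,
    load_checkpoint,
    lstm_step,
    multitask_forward,
    pooled_risk,
    save_checkpoint,
    step_risk,
)
from chrononet.preprocess import PaddedBatch


def _params(d=3, d_h=4, d_a=3, seed=0, **kw):
    return ChronoNetParams(ModelConfig(d=d, d_h=d_h, d_a=d_a, seed=seed, **kw))


def _zero_params(d=1, d_h=1, d_a=1):
    p = _params(d, d_h, d_a)
    for t in p.tensors.values():
        t.value = np.zeros_like(t.value)
    return p


def _batch(X, mask=None, y=None):
    B, T, _ = X.shape
    mask = np.ones((B, T), bool) if mask is None else mask
    y = np.zeros((B, T)) if y is None else y
    return PaddedBatch(X, mask, y, mask.sum(axis=1))


class TestLSTMStep:
    def test_zero_everything_is_a_fixed_point(self):
        p = _zero_params()
        s = lstm_step(np.zeros((1, 1)), EncoderState(np.zeros((1, 1)),
                                                     np.zeros((1, 1))), p)
        assert ad.value_of(s.h).item() == 0 and ad.value_of(s.c).item() == 0

    def test_scalar_hand_evaluation(self):
        # all weights zero, candidate bias large: i = f = o = 0.5,
        # cand -> ~1, so c' = 0.5 and h' = 0.5 tanh(0.5)
        p = _zero_params()
        p.tensors["b_c"].value = np.array([50.0])
        s = lstm_step(np.zeros((1, 1)),
                      EncoderState(np.zeros((1, 1)), np.zeros((1, 1))), p)
        assert ad.value_of(s.c).item() == pytest.approx(0.5, abs=1e-12)
        assert ad.value_of(s.h).item() == pytest.approx(
            0.5 * np.tanh(0.5), abs=1e-12)

    def test_gates_strictly_interior(self):
        p = _params(seed=5)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 3)) * 10
        s = lstm_step(x, EncoderState(np.zeros((4, 4)), np.zeros((4, 4))), p)
        c = ad.value_of(s.c)
        h = ad.value_of(s.h)
        assert np.all(np.abs(np.tanh(c)) < 1)
        assert np.all(np.abs(h) < 1)

    def test_nonfinite_input_rejected(self):
        p = _params()
        x = np.full((1, 3), np.nan)
        with pytest.raises(FloatingPointError, match="step 7"):
            lstm_step(x, EncoderState(np.zeros((1, 4)), np.zeros((1, 4))),
                      p, step_index=7)


class TestEncoder:
    def test_single_step_equals_one_cell_update(self):
        p = _params(seed=1)
        X = np.random.default_rng(1).standard_normal((2, 1, 3))
        H = encode_sequence(_batch(X), p)
        s = lstm_step(X[:, 0, :], EncoderState(np.zeros((2, 4)),
                                               np.zeros((2, 4))), p)
        np.testing.assert_allclose(ad.value_of(H)[:, 0], ad.value_of(s.h))

    def test_identical_rows_encode_identically(self):
        p = _params(seed=2)
        x = np.random.default_rng(2).standard_normal((1, 6, 3))
        X = np.repeat(x, 3, axis=0)
        H = ad.value_of(encode_sequence(_batch(X), p))
        np.testing.assert_array_equal(H[0], H[1])
        np.testing.assert_array_equal(H[0], H[2])

    def test_padding_does_not_change_real_steps(self):
        p = _params(seed=3)
        rng = np.random.default_rng(3)
        X = rng.standard_normal((1, 5, 3))
        H_plain = ad.value_of(encode_sequence(_batch(X), p))
        Xp = np.concatenate([X, rng.standard_normal((1, 3, 3))], axis=1)
        mask = np.zeros((1, 8), bool)
        mask[0, :5] = True
        H_pad = ad.value_of(encode_sequence(_batch(Xp, mask), p))
        np.testing.assert_allclose(H_pad[0, :5], H_plain[0], atol=1e-14)
        # padded steps carry the last real state forward
        np.testing.assert_allclose(H_pad[0, 5:],
                                   np.tile(H_plain[0, -1], (3, 1)),
                                   atol=1e-14)


class TestRiskHeads:
    def test_zero_head_gives_half(self):
        p = _zero_params(d_h=4)
        assert ad.value_of(step_risk(np.zeros((1, 4)), p)).item() == 0.5

    def test_large_bias_saturates(self):
        p = _zero_params(d_h=2)
        p.tensors["b_out"].value = np.array([40.0])
        assert ad.value_of(step_risk(np.zeros((1, 2)), p)).item() == \
            pytest.approx(1.0, abs=1e-12)

    def test_log_odds_hand_value(self):
        p = _zero_params(d_h=3)
        p.tensors["W_out"].value = np.array([[1.0, 0.0, 0.0]])
        h = np.array([[np.log(3.0), 5.0, -2.0]])
        assert ad.value_of(step_risk(h, p)).item() == pytest.approx(0.75)

    def test_multitask_heads_isolated(self):
        p = _params(seed=4)
        h = np.random.default_rng(4).standard_normal((2, 4))
        base = ad.value_of(multitask_forward(h, p)).copy()
        p.tensors["W_task"].value[1] += 0.5
        bumped = ad.value_of(multitask_forward(h, p))
        np.testing.assert_array_equal(bumped[:, 0], base[:, 0])
        np.testing.assert_array_equal(bumped[:, 2], base[:, 2])
        assert not np.allclose(bumped[:, 1], base[:, 1])

    def test_zero_task_heads_give_half(self):
        p = _zero_params(d_h=4)
        np.testing.assert_array_equal(
            ad.value_of(multitask_forward(np.zeros((2, 4)), p)), 0.5)


class TestAttention:
    def test_singleton_sequence_gets_all_weight(self):
        p = _params(seed=5)
        H = np.random.default_rng(5).standard_normal((2, 1, 4))
        a = ad.value_of(attention_weights(H, p))
        np.testing.assert_allclose(a, 1.0)

    def test_identical_states_uniform(self):
        p = _params(seed=6)
        h = np.random.default_rng(6).standard_normal((1, 1, 4))
        H = np.repeat(h, 5, axis=1)
        a = ad.value_of(attention_weights(H, p))
        np.testing.assert_allclose(a, 0.2, atol=1e-12)

    def test_softmax_hand_values(self):
        scores = np.array([[np.log(2.0), 0.0, 0.0]])
        a = ad.value_of(ad.softmax_masked(scores, np.ones((1, 3), bool)))
        np.testing.assert_allclose(a, [[0.5, 0.25, 0.25]], atol=1e-12)

    def test_normalization_and_padding(self):
        p = _params(seed=7)
        H = np.random.default_rng(7).standard_normal((3, 6, 4)) * 3
        mask = np.ones((3, 6), bool)
        mask[1, 4:] = False
        a = ad.value_of(attention_weights(H, p, mask))
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-10)
        assert (a[1, 4:] == 0).all()
        assert (a >= 0).all()

    def test_fully_padded_rejected(self):
        p = _params(seed=8)
        H = np.zeros((1, 4, 4))
        with pytest.raises(UndefinedAttentionError):
            attention_weights(H, p, np.zeros((1, 4), bool))

    def test_adaptive_query_uses_context(self):
        p = _params(seed=9, adaptive_attention=True, d_z=2)
        H = np.random.default_rng(9).standard_normal((2, 5, 4))
        z1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        a1 = ad.value_of(attention_weights(H, p, z=z1))
        a2 = ad.value_of(attention_weights(H, p, z=z1 * 2))
        np.testing.assert_allclose(a1.sum(axis=1), 1.0, atol=1e-10)
        assert not np.allclose(a1, a2)

    def test_context_vector_selection_and_mean(self):
        H = np.arange(24, dtype=float).reshape(1, 6, 4)
        one_hot = np.zeros((1, 6))
        one_hot[0, 2] = 1.0
        np.testing.assert_array_equal(
            ad.value_of(context_vector(H, one_hot))[0], H[0, 2])
        uniform = np.full((1, 6), 1 / 6)
        np.testing.assert_allclose(
            ad.value_of(context_vector(H, uniform))[0], H[0].mean(axis=0))

    def test_context_matches_bruteforce_weighted_sum(self):
        rng = np.random.default_rng(10)
        H = rng.standard_normal((1, 3, 2))
        a = rng.dirichlet(np.ones(3)).reshape(1, 3)
        expected = sum(a[0, t] * H[0, t] for t in range(3))
        np.testing.assert_allclose(
            ad.value_of(context_vector(H, a))[0], expected, atol=1e-14)

    def test_pooled_risk_consistent_with_step_risk(self):
        p = _params(seed=11)
        H = np.random.default_rng(11).standard_normal((1, 4, 4))
        one_hot = np.zeros((1, 4))
        one_hot[0, 2] = 1.0
        c = context_vector(H, one_hot)
        np.testing.assert_allclose(ad.value_of(pooled_risk(c, p)),
                                   ad.value_of(step_risk(H[:, 2, :], p)))


class TestGradients:
    def test_full_model_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        B, T, d, d_h, d_a = 2, 5, 3, 4, 3
        p = _params(d, d_h, d_a, seed=1)
        X = rng.standard_normal((B, T, d))
        mask = np.ones((B, T), bool)
        mask[1, 3:] = False
        y = rng.integers(0, 2, (B, T)).astype(float)
        tt = rng.integers(0, 2, (B, 3)).astype(float)
        batch = PaddedBatch(X, mask, y, mask.sum(axis=1))

        def loss_fn():
            H = encode_sequence(batch, p)
            yh = step_risk(H, p)
            data = bce_sequence(y, yh, mask)
            alpha = attention_weights(H, p, mask)
            ent = attention_entropy_term(alpha, 0.1)
            sm = smoothness_penalty(yh, mask, 0.5)
            c = context_vector(H, alpha)
            pl = bce_sequence(np.array([[1.0], [0.0]]),
                              pooled_risk(c, p).reshape(-1, 1))
            probs = multitask_forward(c, p)
            tls = [bce_sequence(tt[:, k].reshape(-1, 1),
                                probs[:, k].reshape(-1, 1)) for k in range(3)]
            mt = multitask_loss(tls, LossConfig(use_uncertainty=True),
                                log_sigma=p.log_sigma)
            tot, _ = total_loss(data + pl + mt, p,
                                LossConfig(l2_lambda=0.01), sm, ent)
            return tot

        assert gradient_check(loss_fn, p) < 1e-4


class TestCheckpoint:
    def test_bit_exact_round_trip(self, tmp_path):
        p = _params(seed=12)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(p, path)
        q = load_checkpoint(path)
        assert q.config == p.config
        for k, t in p.tensors.items():
            assert np.array_equal(q.tensors[k].value, t.value)
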