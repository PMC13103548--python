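"""Bidirectional attention LSTM."""
import numpy as np
import pytest

from mdefusion.balstm import (BALSTM, BALSTMConfig, balstm_forward,
                              bilstm_layer, input_attention, lstm_cell)
from mdefusion.nn.layers import LSTMDirection
from mdefusion.types import ConfigurationError, ParameterError


def _weights(rng, d, h):
    return {"wx": rng.normal(scale=0.4, size=(d, 4 * h)),
            "wh": rng.normal(scale=0.4, size=(h, 4 * h)),
            "b": rng.normal(scale=0.1, size=4 * h)}


class TestCell:
    def test_memory_preserved_when_forget_saturates(self, rng):
        """Large forget bias and large negative input-gate bias drive
        f -> 1, p -> 0, so c_t = c_{t-1}."""
        d, h = 3, 4
        w = _weights(rng, d, h)
        w["wx"][:] = 0
        w["wh"][:] = 0
        w["b"][:h] = -30.0       # input gate shut
        w["b"][h:2 * h] = 30.0   # forget gate open
        c0 = rng.normal(size=h)
        _, c1 = lstm_cell(rng.normal(size=d), (np.zeros(h), c0), w)
        assert np.abs(c1 - c0).max() < 1e-6

    def test_gates_strictly_in_unit_interval(self, rng):
        d, h = 3, 4
        w = _weights(rng, d, h)
        x = rng.normal(size=d)
        hprev = rng.normal(size=h)
        z = x @ w["wx"] + hprev @ w["wh"] + w["b"]
        gates = 1 / (1 + np.exp(-z[: 2 * h]))
        assert np.all((gates > 0) & (gates < 1))

    def test_matches_stepwise_hand_reference(self, rng):
        """3-unit cell against an explicitly hand-rolled gate-by-gate
        computation of the same update."""
        d, h = 2, 3
        w = _weights(rng, d, h)
        x = rng.normal(size=d)
        h0 = rng.normal(size=h)
        c0 = rng.normal(size=h)
        got_h, got_c = lstm_cell(x, (h0, c0), w)
        z = x @ w["wx"] + h0 @ w["wh"] + w["b"]
        sig = lambda v: 1 / (1 + np.exp(-v))
        p = sig(z[:h])
        f = sig(z[h:2 * h])
        g = np.tanh(z[2 * h:3 * h])
        o = sig(z[3 * h:])
        c1 = f * c0 + p * g
        h1 = o * np.tanh(c1)
        assert np.abs(got_c - c1).max() < 1e-10
        assert np.abs(got_h - h1).max() < 1e-10

    def test_shape_mismatch_rejected(self, rng):
        w = _weights(rng, 2, 3)
        with pytest.raises(ParameterError):
            lstm_cell(rng.normal(size=5), (np.zeros(3), np.zeros(3)), w)


class TestBiLayer:
    def test_palindrome_symmetry(self, rng):
        """With shared weights, processing a palindromic sequence backward
        gives the time-reversed forward outputs."""
        w = _weights(rng, 2, 3)
        half = rng.normal(size=(4, 2))
        seq = np.vstack([half, half[::-1]])
        fwd, bwd = bilstm_layer(seq, w)
        assert np.abs(bwd - fwd[::-1]).max() < 1e-10

    def test_length_one_directions_agree(self, rng):
        w = _weights(rng, 2, 3)
        fwd, bwd = bilstm_layer(rng.normal(size=(1, 2)), w)
        assert np.abs(fwd - bwd).max() < 1e-12

    def test_unrolled_cell_oracle(self, rng):
        w = _weights(rng, 2, 3)
        seq = rng.normal(size=(3, 2))
        fwd, bwd = bilstm_layer(seq, w)
        h = np.zeros(3); c = np.zeros(3)
        for t in range(3):
            h, c = lstm_cell(seq[t], (h, c), w)
            assert np.abs(fwd[t] - h).max() < 1e-12
        h = np.zeros(3); c = np.zeros(3)
        for t in (2, 1, 0):
            h, c = lstm_cell(seq[t], (h, c), w)
            assert np.abs(bwd[t] - h).max() < 1e-12

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ParameterError):
            bilstm_layer(np.empty((0, 2)), _weights(rng, 2, 3))

    def test_forward_causality(self, rng):
        """Permuting future inputs never changes earlier forward states."""
        w = _weights(rng, 2, 3)
        seq = rng.normal(size=(6, 2))
        fwd, _ = bilstm_layer(seq, w)
        seq2 = seq.copy()
        seq2[4:] = seq2[4:][::-1]
        fwd2, _ = bilstm_layer(seq2, w)
        assert np.abs(fwd[:4] - fwd2[:4]).max() < 1e-12

    def test_cell_state_bounded_on_long_sequences(self, rng):
        """|c_t| grows at most linearly: with f<1 the recursion
        c_t = f c_{t-1} + p tanh(g) is bounded by t at worst."""
        w = _weights(rng, 2, 4)
        h = np.zeros(4); c = np.zeros(4)
        x = rng.normal(size=(10_000, 2))
        for t in range(10_000):
            h, c = lstm_cell(x[t], (h, c), w)
            assert np.all(np.isfinite(c))
        assert np.abs(c).max() <= 10_000


class TestAttention:
    def test_constant_scores_give_uniform_weights(self):
        h = np.ones((4, 3))
        x = np.ones((4, 2))
        proj = np.zeros((2, 3))
        out = input_attention(h, x, proj)
        assert np.allclose(out, 1.0 / 3.0)

    def test_weights_sum_to_one(self, rng):
        h = rng.normal(size=(5, 4))
        x = rng.normal(size=(5, 6))
        proj = rng.normal(size=(6, 4))
        out = input_attention(np.ones((5, 4)), x, proj)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_closed_form_softmax(self):
        """Scores (1,2,3) with unit h: softmax = (0.0900, 0.2447, 0.6652)."""
        h = np.ones((1, 3))
        x = np.array([[1.0, 2.0, 3.0]])
        out = input_attention(h, x, np.eye(3))
        assert np.allclose(out[0], [0.0900, 0.2447, 0.6652], atol=1e-4)

    def test_reweighting_preserves_sign(self, rng):
        h = np.abs(rng.normal(size=(4, 5))) + 0.1
        x = rng.normal(size=(4, 5))
        out = input_attention(h, x, rng.normal(size=(5, 5)))
        assert np.all(out > 0)

    def test_misaligned_lengths_rejected(self, rng):
        with pytest.raises(ParameterError):
            input_attention(np.ones((4, 3)), np.ones((5, 2)), np.zeros((2, 3)))


class TestBALSTM:
    def test_output_width_is_twice_hidden(self, rng):
        model = BALSTM(BALSTMConfig(hidden=64, layers=3, input_dim=10, seed=0))
        out = balstm_forward(rng.normal(size=(6, 10)), model)
        assert out.shape == (6, 128)

    def test_deterministic_under_seed(self, rng):
        cfg = BALSTMConfig(hidden=8, layers=3, input_dim=5, seed=4)
        a = BALSTM(cfg)
        b = BALSTM(cfg)
        x = rng.normal(size=(4, 5))
        assert np.array_equal(balstm_forward(x, a), balstm_forward(x, b))

    def test_fewer_than_two_layers_rejected(self):
        with pytest.raises(ConfigurationError):
            BALSTMConfig(hidden=4, layers=1, input_dim=3).validate()

    def test_composition_matches_functional_oracles(self, rng):
        """A 2-layer mini-config equals the composition of the numpy
        bilstm_layer and input_attention oracles with copied weights."""
        cfg = BALSTMConfig(hidden=3, layers=2, input_dim=2, seed=9)
        model = BALSTM(cfg)
        seq = rng.normal(size=(2, 2)).astype(np.float32)
        got = balstm_forward(seq, model)

        def w(ld: LSTMDirection):
            return {"wx": ld.wx.data.astype(float),
                    "wh": ld.wh.data.astype(float),
                    "b": ld.b.data.astype(float)}

        x = seq.astype(float)
        fwd, _ = bilstm_layer(x, w(model.fwd[0]))
        _, bwd = bilstm_layer(x, w(model.bwd[0]))
        hf = input_attention(fwd, x, model.att_fwd[0].proj.w.data.astype(float),
                             model.att_fwd[0].proj.b.data.astype(float))
        hb = input_attention(bwd, x, model.att_bwd[0].proj.w.data.astype(float),
                             model.att_bwd[0].proj.b.data.astype(float))
        x1 = np.hstack([hf, hb])
        fwd2, _ = bilstm_layer(x1, w(model.fwd[1]))
        _, bwd2 = bilstm_layer(x1, w(model.bwd[1]))
        expect = np.hstack([fwd2, bwd2])
        assert np.abs(got - expect).max() < 1e-6
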