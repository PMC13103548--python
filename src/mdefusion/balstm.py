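"""Bidirectional attention LSTM (BALSTM).

Three stacked bidirectional LSTM layers. The first two layers in each
direction are "internal hidden layers": their hidden-state output is
reweighted by input-guided attention — per time step, the layer's own
input is linearly projected to the hidden width, passed through a softmax
across features, and multiplied elementwise into the hidden state. The
final layer's forward and backward hidden sequences are concatenated into
the per-step output (width 2 x hidden).

The printed gate equations give only the input-path contribution; the
cells here carry the standard recurrent terms as well (the memory update
c_t = f*c_{t-1} + p*tanh(g) is only consistent with hidden states that
feed back), with sigmoid gates and tanh cell nonlinearities.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .nn.autograd import Tensor, concat, no_grad, softmax
from .nn.layers import Linear, LSTMDirection, Module
from .types import ConfigurationError, ParameterError


@dataclass(frozen=True)
class BALSTMConfig:
    hidden: int = 64
    layers: int = 3
    input_dim: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.layers < 2:
            raise ConfigurationError(
                "need >= 2 layers (attention applies to the first two)")
        if min(self.hidden, self.input_dim) < 1:
            raise ConfigurationError("hidden and input_dim must be positive")


class InputAttention(Module):
    """h_bar = h * softmax(proj(x)), softmax across the feature dimension."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.proj = Linear(d_in, hidden, rng)
        self.d_in, self.hidden = d_in, hidden

    def __call__(self, h: Tensor, x: Tensor) -> Tensor:
        if h.shape[:-1] != x.shape[:-1]:
            raise ParameterError("h and x must be time-aligned")
        weights = softmax(self.proj(x), axis=-1)
        return h * weights

    def flops(self, t: int, n: int = 1) -> int:
        return n * (self.proj.flops(t) + t * 4 * self.hidden)


class BALSTM(Module):
    def __init__(self, cfg: BALSTMConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.fwd: List[LSTMDirection] = []
        self.bwd: List[LSTMDirection] = []
        self.att_fwd: List[InputAttention] = []
        self.att_bwd: List[InputAttention] = []
        d_in = cfg.input_dim
        for layer in range(cfg.layers):
            self.fwd.append(LSTMDirection(d_in, cfg.hidden, rng))
            self.bwd.append(LSTMDirection(d_in, cfg.hidden, rng))
            if layer < cfg.layers - 1:       # internal hidden layers only
                self.att_fwd.append(InputAttention(d_in, cfg.hidden, rng))
                self.att_bwd.append(InputAttention(d_in, cfg.hidden, rng))
            d_in = 2 * cfg.hidden

    def forward(self, seq: Tensor) -> Tensor:
        """seq (T, N, input_dim) -> per-step output (T, N, 2*hidden)."""
        if seq.shape[0] < 1:
            raise ParameterError("empty sequence")
        x = seq
        n_attended = len(self.att_fwd)
        for layer in range(self.cfg.layers):
            hf = self.fwd[layer](x)
            hb = self.bwd[layer](x.flip0()).flip0()
            if layer < n_attended:
                hf = self.att_fwd[layer](hf, x)
                hb = self.att_bwd[layer](hb, x)
            x = concat([hf, hb], axis=2)
        return x

    __call__ = forward

    def flops(self, t: int, n: int = 1) -> int:
        total = 0
        for layer in range(self.cfg.layers):
            total += self.fwd[layer].flops(t, n) + self.bwd[layer].flops(t, n)
        for att in (*self.att_fwd, *self.att_bwd):
            total += att.flops(t, n)
        return total


# ---------------------------------------------------------------------------
# functional views used by the oracles in the test-suite and by callers that
# want single-sequence numpy semantics

def lstm_cell(x_t: np.ndarray, state: Tuple[np.ndarray, np.ndarray],
              weights: Dict[str, np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    """One LSTM step on a single vector; weights {wx (D,4H), wh (H,4H), b (4H)}.

    Gate order p (input), f (forget), g (candidate), o (output);
    c_t = f c_{t-1} + p tanh(g), h_t = o tanh(c_t).
    """
    h_prev, c_prev = (np.asarray(s, float) for s in state)
    wx, wh, b = (np.asarray(weights[k], float) for k in ("wx", "wh", "b"))
    H = wh.shape[0]
    if wx.shape[1] != 4 * H or b.shape[0] != 4 * H:
        raise ParameterError("inconsistent weight shapes")
    if x_t.shape[-1] != wx.shape[0] or h_prev.shape[-1] != H:
        raise ParameterError("input/state dimensions do not match weights")
    z = x_t @ wx + h_prev @ wh + b
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    p, f, g, o = z[..., :H], z[..., H:2 * H], z[..., 2 * H:3 * H], z[..., 3 * H:]
    c = sig(f) * c_prev + sig(p) * np.tanh(g)
    h = sig(o) * np.tanh(c)
    return h, c


def bilstm_layer(seq: np.ndarray, weights_fwd: Dict[str, np.ndarray],
                 weights_bwd: Optional[Dict[str, np.ndarray]] = None
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Run one bidirectional layer over (T, D); outputs aligned to input time.

    The backward pass processes the reversed sequence, so its recurrence
    uses the c_{t+1} ordering; ``weights_bwd`` defaults to sharing
    ``weights_fwd``.
    """
    seq = np.asarray(seq, float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ParameterError("seq must be a nonempty (T, D) array")
    if weights_bwd is None:
        weights_bwd = weights_fwd
    H = weights_fwd["wh"].shape[0]

    def run(s, w):
        h = np.zeros(H)
        c = np.zeros(H)
        out = []
        for t in range(s.shape[0]):
            h, c = lstm_cell(s[t], (h, c), w)
            out.append(h)
        return np.stack(out)

    fwd = run(seq, weights_fwd)
    bwd = run(seq[::-1], weights_bwd)[::-1]
    return fwd, bwd


def input_attention(h: np.ndarray, x: np.ndarray, proj: np.ndarray,
                    bias: Optional[np.ndarray] = None) -> np.ndarray:
    """Numpy view of the attention reweighting (softmax across features)."""
    h = np.asarray(h, float)
    x = np.asarray(x, float)
    if h.shape[0] != x.shape[0]:
        raise ParameterError("h and x must have equal time length")
    scores = x @ np.asarray(proj, float)
    if bias is not None:
        scores = scores + bias
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    return h * (e / e.sum(axis=-1, keepdims=True))


def balstm_forward(seq: np.ndarray, model: BALSTM) -> np.ndarray:
    """Single-sequence forward through a BALSTM: (T, D) -> (T, 2*hidden)."""
    with no_grad():
        out = model(Tensor(np.asarray(seq, dtype=np.float32)[:, None, :]))
    return out.data[:, 0, :]
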