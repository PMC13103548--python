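"""Half-split crossover sparse autoencoder (HCSAE).

The fusion engine: each feature stream (time-frequency F1, spatial F2) is
abstracted by a 1x1 channel-mixing convolution followed by 1x3 temporal
convolutions (tanh throughout); the two abstracted maps are bisected along
channels and cross-combined (first half of one with second half of the
other), sparsified by inverted dropout, fused pairwise in a small tree of
1x1 convolutions, and decoded back to the abstracted width with max-pooled
scale reduction. Sparsity comes from dropout alone — no KL activation
penalty — because the 1/(1-q) rescaling keeps activation expectations
unchanged between training and inference.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .nn.autograd import Tensor, concat, max_pool1d, mse, no_grad
from .nn.layers import Conv1d, Module
from .types import ConfigurationError, FeatureSet, ParameterError

ArrayOrTensor = Union[np.ndarray, Tensor]


@dataclass(frozen=True)
class HCSAEConfig:
    abstract_channels: int = 32
    n_1x3_layers: int = 2
    dropout_q: float = 0.3
    latent_channels: int = 64
    recon_weight: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.abstract_channels % 2 != 0:
            raise ConfigurationError("abstract_channels must be even (half-split)")
        if not 0.0 <= self.dropout_q < 1.0:
            raise ParameterError("dropout_q must be in [0, 1)")
        if self.recon_weight < 0:
            raise ParameterError("recon_weight must be >= 0")
        if min(self.abstract_channels, self.latent_channels, self.n_1x3_layers + 1) < 1:
            raise ConfigurationError("layer sizes must be positive")


@dataclass
class Reconstruction:
    output: np.ndarray
    recon_error: float


def tanh_activation(x: ArrayOrTensor) -> ArrayOrTensor:
    """Elementwise tanh; the symmetric activation used throughout the HCSAE."""
    if isinstance(x, Tensor):
        return x.tanh()
    return np.tanh(np.asarray(x, dtype=float))


def dropout_sparsify(f: np.ndarray, q: float, training: bool = True,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Inverted dropout: Bernoulli(1-q) mask scaled by 1/(1-q) in training,
    identity at inference (the scaling already preserves expectations)."""
    if not 0.0 <= q < 1.0:
        raise ParameterError("q must be in [0, 1)")
    f = np.asarray(f, dtype=float)
    if not training or q == 0.0:
        return f.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = rng.random(f.shape) >= q
    return f * mask / (1.0 - q)


def half_split_crossover(A: ArrayOrTensor, B: ArrayOrTensor,
                         axis: int = 0) -> Tuple[ArrayOrTensor, ArrayOrTensor]:
    """Bisect A and B along the channel axis and swap second halves:
    P = [A1, B2], Q = [B1, A2]. Values are regrouped, never transformed."""
    a_shape = A.shape
    if a_shape != B.shape:
        raise ParameterError("A and B must have identical shapes")
    c = a_shape[axis]
    if c % 2 != 0:
        raise ConfigurationError("channel count must be even for the half-split")
    h = c // 2
    if isinstance(A, Tensor) or isinstance(B, Tensor):
        sl1 = [slice(None)] * len(a_shape)
        sl2 = [slice(None)] * len(a_shape)
        sl1[axis] = slice(0, h)
        sl2[axis] = slice(h, c)
        A1, A2 = A[tuple(sl1)], A[tuple(sl2)]
        B1, B2 = B[tuple(sl1)], B[tuple(sl2)]
        return concat([A1, B2], axis=axis), concat([B1, A2], axis=axis)
    A1, A2 = np.split(np.asarray(A), 2, axis=axis)
    B1, B2 = np.split(np.asarray(B), 2, axis=axis)
    return (np.concatenate([A1, B2], axis=axis),
            np.concatenate([B1, A2], axis=axis))


class HCSAE(Module):
    """The full autoencoder; operates on batches (N, channels, T)."""

    def __init__(self, d_f1: int, d_f2: int, cfg: HCSAEConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        A = cfg.abstract_channels
        self.in1 = Conv1d(d_f1, A, 1, rng)
        self.in2 = Conv1d(d_f2, A, 1, rng)
        self.deep1 = [Conv1d(A, A, 3, rng) for _ in range(cfg.n_1x3_layers)]
        self.deep2 = [Conv1d(A, A, 3, rng) for _ in range(cfg.n_1x3_layers)]
        self.fuse_p = Conv1d(A, A, 1, rng)
        self.fuse_q = Conv1d(A, A, 1, rng)
        self.fuse_top = Conv1d(2 * A, cfg.latent_channels, 1, rng)
        self.decode_conv = Conv1d(cfg.latent_channels, 2 * A, 1, rng)
        self.d_f1, self.d_f2 = d_f1, d_f2

    # -- stages -----------------------------------------------------------
    def abstract(self, F1: Tensor, F2: Tensor) -> Tuple[Tensor, Tensor]:
        a = self.in1(F1).tanh()
        for conv in self.deep1:
            a = conv(a).tanh()
        b = self.in2(F2).tanh()
        for conv in self.deep2:
            b = conv(b).tanh()
        return a, b

    def _dropout(self, x: Tensor, training: bool,
                 rng: Optional[np.random.Generator]) -> Tensor:
        q = self.cfg.dropout_q
        if not training or q == 0.0:
            return x
        if rng is None:
            rng = np.random.default_rng(self.cfg.seed)
        mask = (rng.random(x.shape) >= q).astype(np.float32) / np.float32(1.0 - q)
        return x * Tensor(mask)

    def fuse(self, P: Tensor, Q: Tensor, training: bool = False,
             rng: Optional[np.random.Generator] = None) -> Tensor:
        P = self._dropout(P, training, rng)
        Q = self._dropout(Q, training, rng)
        lp = self.fuse_p(P).tanh()
        lq = self.fuse_q(Q).tanh()
        return self.fuse_top(concat([lp, lq], axis=1)).tanh()

    def decode(self, z: Tensor, ab: Tensor) -> Tuple[Tensor, Tensor]:
        """Restore the abstracted width, pool time by 2; reconstruction
        target is the same-pooled concatenated abstracted input."""
        restored = max_pool1d(self.decode_conv(z).tanh(), 2, 2)
        with no_grad():
            target = max_pool1d(Tensor(ab.data), 2, 2).data
        return restored, mse(restored, target)

    def forward(self, F1: Tensor, F2: Tensor, training: bool = False,
                rng: Optional[np.random.Generator] = None
                ) -> Tuple[Tensor, Tensor, Tensor]:
        """Returns (latent, reconstruction, recon_error-loss-Tensor)."""
        a, b = self.abstract(F1, F2)
        P, Q = half_split_crossover(a, b, axis=1)
        z = self.fuse(P, Q, training=training, rng=rng)
        recon, err = self.decode(z, concat([a, b], axis=1))
        return z, recon, err

    def flops(self, t: int, n: int = 1) -> int:
        convs = [self.in1, self.in2, *self.deep1, *self.deep2,
                 self.fuse_p, self.fuse_q, self.fuse_top, self.decode_conv]
        total = sum(c.flops(t) for c in convs)
        total += 2 * self.cfg.abstract_channels * (t // 2)  # max-pool compares
        return n * total


# ---------------------------------------------------------------------------
# functional wrappers over a model instance (single segment, no batch axis)

def _to_batch(x: np.ndarray) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float32)[None, ...])


def abstract_features(F1: np.ndarray, F2: np.ndarray, model: HCSAE
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Run the abstraction stage on one segment's (channels, T) streams."""
    with no_grad():
        a, b = model.abstract(_to_batch(F1), _to_batch(F2))
    return a.data[0], b.data[0]


def tree_fuse(P: np.ndarray, Q: np.ndarray, model: HCSAE, training: bool = False,
              seed: Optional[int] = None) -> np.ndarray:
    rng = np.random.default_rng(seed) if seed is not None else None
    with no_grad():
        z = model.fuse(_to_batch(P), _to_batch(Q), training=training, rng=rng)
    return z.data[0]


def decode_reconstruct(z: np.ndarray, ab: np.ndarray, model: HCSAE) -> Reconstruction:
    with no_grad():
        recon, err = model.decode(_to_batch(z), _to_batch(ab))
    return Reconstruction(output=recon.data[0], recon_error=float(err.data))


def hcsae_forward(fs: FeatureSet, model: HCSAE, training: bool = False,
                  seed: Optional[int] = None) -> Tuple[np.ndarray, Reconstruction]:
    """Full pass for one FeatureSet: latent code + reconstruction."""
    F1 = fs.F1.reshape(-1, fs.F1.shape[-1])   # (C*B, T)
    F2 = fs.F2
    rng = np.random.default_rng(seed) if seed is not None else None
    with no_grad():
        z, recon, err = model.forward(_to_batch(F1), _to_batch(F2),
                                      training=training, rng=rng)
    return z.data[0], Reconstruction(output=recon.data[0],
                                     recon_error=float(err.data))
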