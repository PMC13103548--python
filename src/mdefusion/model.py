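"""MDEFusion: HCSAE fusion front end + BALSTM temporal model + classifier.

The fused latent sequence from the HCSAE feeds the bidirectional attention
LSTM; per-step outputs are mean-pooled over time and a single fully
connected layer produces the two-class logits. Training minimizes

    cross-entropy + recon_weight * reconstruction MSE

end to end with Adam (batch size 64 and learning rate 1e-3 as defaults) and an exponential learning-rate decay of x0.9 every 20 epochs.

Feature maps are condensed to a fixed sequence length (mean pooling over
equal time bins) before entering the network; ``seq_len`` is a model
hyperparameter, not a property of the data.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .balstm import BALSTM, BALSTMConfig
from .hcsae import HCSAE, HCSAEConfig
from .nn.autograd import Tensor, cross_entropy, no_grad
from .nn.layers import Adam, Linear, Module
from .types import (ConfigurationError, DivergenceError, ParameterError)


@dataclass(frozen=True)
class ModelConfig:
    hcsae: HCSAEConfig = field(default_factory=HCSAEConfig)
    balstm: BALSTMConfig = field(default_factory=BALSTMConfig)
    d_f1: int = 152             # flattened F1 channels (19 ch x 8 subbands)
    d_f2: int = 19              # ICA components
    seq_len: int = 32           # network-side temporal condensation
    lr: float = 1e-3
    batch: int = 64
    epochs: int = 200
    decay: float = 0.9
    decay_every: int = 20
    seed: int = 0

    def validate(self) -> None:
        if min(self.lr, self.batch, self.epochs, self.seq_len) <= 0:
            raise ParameterError("lr, batch, epochs, seq_len must be positive")
        if not 0 < self.decay <= 1:
            raise ParameterError("decay must be in (0, 1]")
        self.hcsae.validate()
        self.balstm.validate()
        if self.balstm.input_dim != self.hcsae.latent_channels:
            raise ConfigurationError(
                "BALSTM input_dim must equal HCSAE latent_channels")


def condense_time(x: np.ndarray, seq_len: int, mode: str = "abs") -> np.ndarray:
    """Pool the last axis into ``seq_len`` equal bins.

    ``abs`` (default for network inputs) pools the magnitude envelope:
    wavelet subband coefficients and unmixed source activations are
    band-pass waveforms, so a signed mean cancels toward zero and discards
    the amplitude structure the classifier needs. ``mean`` pools the raw
    values (useful for slowly varying features).
    """
    t = x.shape[-1]
    if t < seq_len:
        raise ParameterError(f"cannot condense {t} steps into {seq_len} bins")
    if mode == "abs":
        x = np.abs(x)
    elif mode != "mean":
        raise ParameterError(f"unknown condense mode {mode!r}")
    edges = np.linspace(0, t, seq_len + 1).astype(int)
    return np.stack([x[..., a:b].mean(axis=-1) for a, b in zip(edges[:-1], edges[1:])],
                    axis=-1)


class MDEFusion(Module):
    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        self.hcsae = HCSAE(cfg.d_f1, cfg.d_f2, replace(cfg.hcsae, seed=cfg.seed))
        self.balstm = BALSTM(replace(cfg.balstm, seed=cfg.seed + 1))
        rng = np.random.default_rng(cfg.seed + 2)
        self.head = Linear(2 * cfg.balstm.hidden, 2, rng)

    def forward(self, X1: np.ndarray, X2: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None
                ) -> Tuple[Tensor, Tensor]:
        """X1 (N, d_f1, seq_len), X2 (N, d_f2, seq_len) -> (logits, recon loss)."""
        z, _, recon_err = self.hcsae.forward(
            Tensor(np.ascontiguousarray(X1, dtype=np.float32)),
            Tensor(np.ascontiguousarray(X2, dtype=np.float32)),
            training=training, rng=rng)
        seq = z.transpose(2, 0, 1)            # (T, N, latent)
        out = self.balstm(seq)                # (T, N, 2*hidden)
        pooled = out.mean(axis=0)             # (N, 2*hidden)
        logits = self.head(pooled)
        return logits, recon_err

    def predict_proba(self, X1: np.ndarray, X2: np.ndarray,
                      batch: int = 256) -> np.ndarray:
        probs = []
        with no_grad():
            for a in range(0, X1.shape[0], batch):
                logits, _ = self.forward(X1[a:a + batch], X2[a:a + batch],
                                         training=False)
                z = logits.data - logits.data.max(axis=1, keepdims=True)
                e = np.exp(z)
                probs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(probs)

    def flops(self, seq_len: Optional[int] = None, n: int = 1) -> int:
        t = seq_len or self.cfg.seq_len
        total = self.hcsae.flops(t, n) + self.balstm.flops(t, n)
        total += n * self.head.flops(1)
        return total


def assemble_model(cfg: ModelConfig) -> MDEFusion:
    """Build a seeded MDEFusion; identical cfg -> identical initial weights."""
    return MDEFusion(cfg)


@dataclass
class ComplexityReport:
    params: int
    flops: int


def count_params_flops(model: MDEFusion,
                       seq_len: Optional[int] = None) -> ComplexityReport:
    """Exact trainable-scalar count and per-forward FLOPs (2 per MAC) for
    one segment at the given sequence length."""
    return ComplexityReport(params=model.n_params(),
                            flops=model.flops(seq_len, n=1))


# ---------------------------------------------------------------------------
# training

@dataclass
class History:
    epochs: List[dict] = field(default_factory=list)

    def as_rows(self) -> List[dict]:
        return list(self.epochs)

    @property
    def best_val_acc(self) -> float:
        return max((e["val_acc"] for e in self.epochs), default=float("nan"))


def _accuracy(model: MDEFusion, X1, X2, y, batch: int) -> Tuple[float, float]:
    """Returns (mean CE loss, accuracy) without building graphs."""
    losses = []
    correct = 0
    with no_grad():
        for a in range(0, X1.shape[0], batch):
            logits, _ = model.forward(X1[a:a + batch], X2[a:a + batch])
            z = logits.data - logits.data.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            yy = y[a:a + batch]
            losses.append(-np.log(np.maximum(p[np.arange(len(yy)), yy], 1e-30)))
            correct += int((p.argmax(axis=1) == yy).sum())
    loss = float(np.concatenate(losses).mean())
    return loss, correct / X1.shape[0]


def train(model: MDEFusion, train_data: Tuple[np.ndarray, np.ndarray, np.ndarray],
          val_data: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
          cfg: Optional[ModelConfig] = None,
          epochs: Optional[int] = None) -> Tuple[MDEFusion, History]:
    """End-to-end training; returns the model (restored to the best-validation
    checkpoint when validation data is given) and the per-epoch history.

    ``train_data`` is (X1, X2, y) with integer labels (HC=0, SZ=1).
    """
    cfg = cfg or model.cfg
    n_epochs = epochs if epochs is not None else cfg.epochs
    X1, X2, y = train_data
    if X1.shape[0] == 0:
        raise ParameterError("empty training partition")
    if val_data is not None and val_data[0].shape[0] == 0:
        raise ParameterError("empty validation partition")
    y = np.asarray(y, dtype=np.int64)

    opt = Adam(model.parameters(), lr=cfg.lr)
    shuffle_rng = np.random.default_rng(cfg.seed + 1000)
    dropout_rng = np.random.default_rng(cfg.seed + 2000)
    history = History()
    best_val = -np.inf
    best_state: Optional[Dict[str, np.ndarray]] = None
    lam = cfg.hcsae.recon_weight

    for epoch in range(n_epochs):
        lr = cfg.lr * cfg.decay ** (epoch // cfg.decay_every)
        order = shuffle_rng.permutation(X1.shape[0])
        ep_loss = 0.0
        ep_recon = 0.0
        n_batches = 0
        for a in range(0, len(order), cfg.batch):
            idx = order[a:a + cfg.batch]
            logits, recon_err = model.forward(X1[idx], X2[idx], training=True,
                                              rng=dropout_rng)
            ce = cross_entropy(logits, y[idx])
            loss = ce + lam * recon_err if lam > 0 else ce
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            ep_loss += float(loss.data)
            ep_recon += float(recon_err.data) if lam > 0 else 0.0
            n_batches += 1
        train_loss, train_acc = _accuracy(model, X1, X2, y, 4 * cfg.batch)
        row = {"epoch": epoch, "lr": lr,
               "loss": ep_loss / n_batches,
               "recon": ep_recon / n_batches,
               "train_loss": train_loss, "train_acc": train_acc,
               "val_loss": float("nan"), "val_acc": float("nan")}
        if val_data is not None:
            vy = np.asarray(val_data[2], dtype=np.int64)
            row["val_loss"], row["val_acc"] = _accuracy(
                model, val_data[0], val_data[1], vy, 4 * cfg.batch)
            if row["val_acc"] > best_val:
                best_val = row["val_acc"]
                best_state = model.state_dict()
        history.epochs.append(row)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(model: MDEFusion, path) -> Path:
    """Portable array archive (.npz) plus a JSON manifest alongside."""
    path = Path(path).with_suffix(".npz")
    np.savez(path, **model.state_dict())
    manifest = {
        "format": "mdefusion-checkpoint-v1",
        "params": model.n_params(),
        "config": _config_to_dict(model.cfg),
        "arrays": sorted(k for k, _ in model.named_parameters()),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return path


def load_checkpoint(path) -> MDEFusion:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg = _config_from_dict(manifest["config"])
    model = MDEFusion(cfg)
    with np.load(path) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return model


def _config_to_dict(cfg: ModelConfig) -> dict:
    d = {k: v for k, v in vars(cfg).items() if k not in ("hcsae", "balstm")}
    d["hcsae"] = dict(vars(cfg.hcsae))
    d["balstm"] = dict(vars(cfg.balstm))
    return d


def _config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    hc = HCSAEConfig(**d.pop("hcsae"))
    bl = BALSTMConfig(**d.pop("balstm"))
    return ModelConfig(hcsae=hc, balstm=bl, **d)
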