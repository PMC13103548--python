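"""Parameterized layers and the optimizer built on the autograd core."""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .autograd import Tensor, conv1d, stack0, unbind0


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module base: parameter discovery and state (de)serialization."""

    def named_parameters(self, prefix: str = "") -> List[Tuple[str, Parameter]]:
        out: List[Tuple[str, Parameter]] = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=full + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    q = q[:rows, :cols] if q.shape[0] >= rows else q.T[:rows, :cols]
    return q.astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Parameter(_uniform(rng, (d_in, d_out), d_in))
        self.b = Parameter(np.zeros(d_out, dtype=np.float32))
        self.d_in, self.d_out = d_in, d_out

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def flops(self, n_rows: int) -> int:
        # 2 flops per MAC plus the bias add
        return n_rows * (2 * self.d_in * self.d_out + self.d_out)


class Conv1d(Module):
    """Same-padded temporal convolution over (N, C, T) maps."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.w = Parameter(_uniform(rng, (c_out, c_in, kernel), c_in * kernel))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)

    def flops(self, t: int) -> int:
        return t * (2 * self.c_in * self.c_out * self.kernel + self.c_out)


class LSTMDirection(Module):
    """One direction of one LSTM layer, unrolled over time.

    Gate order in the fused weight matrices: input (p), forget (f),
    candidate (g), output (o). Cell update: c_t = f * c_{t-1} + p * tanh(g);
    hidden: h_t = o * tanh(c_t). Recurrent weights are orthogonal-initialized,
    input weights scaled-uniform, forget-gate bias 1.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.wx = Parameter(_uniform(rng, (d_in, 4 * hidden), d_in))
        wh = np.concatenate([_orthogonal(rng, hidden, hidden) for _ in range(4)],
                            axis=1)
        self.wh = Parameter(wh)
        bias = np.zeros(4 * hidden, dtype=np.float32)
        bias[hidden:2 * hidden] = 1.0   # forget-gate bias
        self.b = Parameter(bias)
        self.d_in, self.hidden = d_in, hidden

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> Tuple[Tensor, Tensor]:
        H = self.hidden
        z = x_t @ self.wx + h @ self.wh + self.b
        p = z[:, :H].sigmoid()
        f = z[:, H:2 * H].sigmoid()
        g = z[:, 2 * H:3 * H].tanh()
        o = z[:, 3 * H:].sigmoid()
        c_new = f * c + p * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def __call__(self, seq: Tensor) -> Tensor:
        """seq: (T, N, d_in) -> hidden sequence (T, N, hidden)."""
        T, N, _ = seq.shape
        h = Tensor(np.zeros((N, self.hidden), dtype=np.float32))
        c = Tensor(np.zeros((N, self.hidden), dtype=np.float32))
        hs = []
        for x_t in unbind0(seq):
            h, c = self.step(x_t, h, c)
            hs.append(h)
        return stack0(hs)

    def flops(self, t: int, n: int = 1) -> int:
        per_step = 2 * (self.d_in + self.hidden) * 4 * self.hidden + 4 * self.hidden
        per_step += 10 * self.hidden   # gate nonlinearities and cell arithmetic
        return t * n * per_step


class Adam:
    """Adam with optional per-call learning rate (for scheduled decay)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
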