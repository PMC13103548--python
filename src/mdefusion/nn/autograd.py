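"""Compact reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the fusion network: a taped ``Tensor`` with the
elementwise/linear-algebra primitives the HCSAE and BALSTM need, plus
fused ops (1-D convolution, softmax, cross-entropy, max-pool) where a
hand-written gradient is both faster and clearer than composition.
Float32 throughout; gradients accumulate in the dtype of the data.
"""
from __future__ import annotations

import contextlib
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Tuple["Tensor", ...] = (),
                 _backward: Optional[Callable[[np.ndarray], None]] = None):
        if isinstance(data, np.ndarray):
            self.data = data
        elif isinstance(data, np.generic):   # numpy scalar: keep its dtype
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _make(self, data, parents, backward) -> "Tensor":
        rg = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=rg,
                     _parents=tuple(p for p in parents if p.requires_grad),
                     _backward=backward if rg else None)
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        o = self._wrap(other)
        out_data = self.data + o.data

        def bw(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o.accumulate(_unbroadcast(g, o.data.shape))
        return self._make(out_data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self.accumulate(-g)
        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)
        out_data = self.data * o.data

        def bw(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o.accumulate(_unbroadcast(g * self.data, o.data.shape))
        return self._make(out_data, (self, o), bw)

    __rmul__ = __mul__

    def __matmul__(self, other):
        o = self._wrap(other)
        out_data = self.data @ o.data

        def bw(g):
            if self.requires_grad:
                self.accumulate(g @ o.data.swapaxes(-1, -2))
            if o.requires_grad:
                go = self.data.swapaxes(-1, -2) @ g
                o.accumulate(_unbroadcast(go, o.data.shape))
        return self._make(out_data, (self, o), bw)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self.accumulate(full)
        return self._make(out_data, (self,), bw)

    # -- nonlinearities ---------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)

        def bw(g):
            self.accumulate(g * (1.0 - y * y))
        return self._make(y, (self,), bw)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self.accumulate(g * y * (1.0 - y))
        return self._make(y, (self,), bw)

    def exp(self):
        y = np.exp(self.data)

        def bw(g):
            self.accumulate(g * y)
        return self._make(y, (self,), bw)

    def log(self):
        def bw(g):
            self.accumulate(g / self.data)
        return self._make(np.log(self.data), (self,), bw)

    # -- reductions / reshaping ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self.accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self.accumulate(np.broadcast_to(gg, self.data.shape).copy())
        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def bw(g):
            self.accumulate(g.reshape(orig))
        return self._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            self.accumulate(g.transpose(inv))
        return self._make(out_data, (self,), bw)

    def flip0(self):
        """Reverse along axis 0 (time reversal for the backward LSTM pass)."""
        out_data = self.data[::-1].copy()

        def bw(g):
            self.accumulate(g[::-1])
        return self._make(out_data, (self,), bw)


# -- multi-input ops -------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t.accumulate(g[tuple(sl)])
    rg = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=rg,
                  _parents=tuple(t for t in tensors if t.requires_grad),
                  _backward=bw if rg else None)


def stack0(tensors: Sequence[Tensor]) -> Tensor:
    """Stack equal-shape tensors along a new leading axis."""
    tensors = list(tensors)
    out_data = np.stack([t.data for t in tensors])

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t.accumulate(g[i])
    rg = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=rg,
                  _parents=tuple(t for t in tensors if t.requires_grad),
                  _backward=bw if rg else None)


def unbind0(x: Tensor) -> List[Tensor]:
    """Split along axis 0 into views sharing one gradient buffer.

    Cheaper than repeated ``x[t]`` inside a time loop: the backward pass
    writes each step's gradient into a single preallocated buffer.
    """
    def make(i):
        def bw(g):
            # write straight into the parent's gradient buffer; reverse
            # topological order guarantees x's own backward runs only after
            # every slice has contributed
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            x.grad[i] += g
        return bw

    return [x._make(x.data[i], (x,), make(i)) for i in range(x.data.shape[0])]


def conv1d(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Same-padded 1-D convolution: x (N, Ci, T), w (Co, Ci, k) -> (N, Co, T).

    Implemented as a sum over kernel taps of channel-mixing matmuls, which
    is efficient for the k in {1, 3} kernels used here.
    """
    N, Ci, T = x.data.shape
    Co, Ci2, k = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input {Ci}, kernel {Ci2}")
    pad = (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    out = np.zeros((N, Co, T), dtype=x.data.dtype)
    for j in range(k):
        out += np.matmul(w.data[:, :, j], xp[:, :, j:j + T])
    if b is not None:
        out += b.data[None, :, None]

    def bw(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, :, j:j + T] += np.matmul(w.data[:, :, j].T, g)
            x.accumulate(gxp[:, :, pad:pad + T] if pad else gxp)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for j in range(k):
                gw[:, :, j] = np.einsum("not,nct->oc", g, xp[:, :, j:j + T],
                                        optimize=True)
            w.accumulate(gw)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2)))
    parents = (x, w) + ((b,) if b is not None else ())
    rg = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    return Tensor(out, requires_grad=rg,
                  _parents=tuple(p for p in parents if p.requires_grad),
                  _backward=bw if rg else None)


def max_pool1d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    """Max-pool along the last axis (kernel == stride, non-overlapping)."""
    if kernel != stride:
        raise ValueError("only kernel == stride pooling is supported")
    N, C, T = x.data.shape
    To = T // kernel
    xv = x.data[:, :, :To * kernel].reshape(N, C, To, kernel)
    arg = xv.argmax(axis=3)
    out = np.take_along_axis(xv, arg[..., None], axis=3)[..., 0]

    def bw(g):
        gx = np.zeros_like(xv)
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=3)
        full = np.zeros_like(x.data)
        full[:, :, :To * kernel] = gx.reshape(N, C, To * kernel)
        x.accumulate(full)
    return x._make(out, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x.accumulate(y * (g - dot))
    return x._make(y, (x,), bw)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, K) logits against integer labels."""
    labels = np.asarray(labels)
    N = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    loss = -np.mean(np.log(np.maximum(p[np.arange(N), labels], 1e-30)))

    def bw(g):
        gp = p.copy()
        gp[np.arange(N), labels] -= 1.0
        logits.accumulate(g * gp / N)
    return logits._make(np.asarray(loss, dtype=logits.data.dtype), (logits,), bw)


def mse(a: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    diff = a.data - target
    loss = np.mean(diff * diff)

    def bw(g):
        a.accumulate(g * 2.0 * diff / diff.size)
    return a._make(np.asarray(loss, dtype=a.data.dtype), (a,), bw)
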