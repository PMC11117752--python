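"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small 3D convolutional encoder-decoder with a
variational branch: broadcast arithmetic, matmul, 3D convolution (kernel 1
or 3, stride 1 or 2, "same" padding), nearest-neighbor x2 upsampling,
sigmoid/relu/exp/log, reductions, reshape and clip.  Gradients are exact
(verified against finite differences in the test suite); everything is
float64 numpy, so runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv3d", "upsample2", "linear", "relu", "sigmoid", "clip"]


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, _parents=parents)
        if out.requires_grad:
            out._backward = backward
        return out

    def _accum(self, g) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def square(self):
        def backward(g):
            self._accum(2.0 * self.data * g)

        return self._make(self.data ** 2, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # ---- shape & reductions ----------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def sum(self):
        def backward(g):
            self._accum(np.broadcast_to(g, self.shape).astype(np.float64))

        return self._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            self._accum(np.broadcast_to(g / n, self.shape).astype(np.float64))

        return self._make(self.data.mean(), (self,), backward)

    # ---- autodiff driver ---------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from a scalar output through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep at full volume sizes
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Reduce a broadcast gradient back to the original operand shape."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    return x._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic (never exponentiates a positive argument)
    d = x.data
    pos = d >= 0
    out_data = np.empty_like(d)
    out_data[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    e = np.exp(d[~pos])
    out_data[~pos] = e / (1.0 + e)

    def backward(g):
        x._accum(g * out_data * (1.0 - out_data))

    return x._make(out_data, (x,), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through-zero gradient outside [lo, hi]."""
    inside = (x.data >= lo) & (x.data <= hi)

    def backward(g):
        x._accum(g * inside)

    return x._make(np.clip(x.data, lo, hi), (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Dense layer on a flat vector: w (m,n) @ x (n,) + b (m,)."""

    def backward(g):
        w._accum(np.outer(g, x.data))
        b._accum(g)
        x._accum(w.data.T @ g)

    return x._make(w.data @ x.data + b.data, (x, w, b), backward)


def _conv_offsets(k: int):
    r = range(k)
    return [(dx, dy, dz) for dx in r for dy in r for dz in r]


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """3D convolution, channels-first single sample.

    x: (C_in, X, Y, Z); w: (C_out, C_in, k, k, k) with k in {1, 3};
    "same" padding (k // 2), stride 1 or 2.  Implemented as one tensordot
    per kernel offset, which keeps both forward and backward BLAS-bound.
    """
    c_in, *sp = x.shape
    c_out, c_in_w, k = w.shape[0], w.shape[1], w.shape[2]
    if c_in_w != c_in:
        raise ValueError(f"conv3d channel mismatch: x has {c_in}, w expects {c_in_w}")
    pad = k // 2
    xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3)
    out_sp = tuple((d + 2 * pad - k) // stride + 1 for d in sp)
    offsets = _conv_offsets(k)

    def off_slice(off):
        return (slice(None),) + tuple(
            slice(o, o + stride * (n - 1) + 1, stride) for o, n in zip(off, out_sp))

    out_data = np.broadcast_to(b.data[:, None, None, None], (c_out,) + out_sp).copy()
    for off in offsets:
        out_data += np.tensordot(w.data[:, :, off[0], off[1], off[2]], xp[off_slice(off)],
                                 axes=([1], [0]))

    def backward(g):
        b._accum(g.sum(axis=(1, 2, 3)))
        gxp = np.zeros_like(xp) if x.requires_grad else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for off in offsets:
            sl = off_slice(off)
            if gw is not None:
                gw[:, :, off[0], off[1], off[2]] = np.tensordot(
                    g, xp[sl], axes=([1, 2, 3], [1, 2, 3]))
            if gxp is not None:
                gxp[sl] += np.tensordot(w.data[:, :, off[0], off[1], off[2]], g,
                                        axes=([0], [0]))
        if gw is not None:
            w._accum(gw)
        if gxp is not None:
            if pad:
                x._accum(gxp[:, pad:-pad, pad:-pad, pad:-pad])
            else:
                x._accum(gxp)

    return x._make(out_data, (x, w, b), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor x2 upsampling of a (C, X, Y, Z) feature map."""
    out_data = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        c, gx, gy, gz = g.shape
        x._accum(g.reshape(c, gx // 2, 2, gy // 2, 2, gz // 2, 2).sum(axis=(2, 4, 6)))

    return x._make(out_data, (x,), backward)
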