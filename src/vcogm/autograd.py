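"""Minimal reverse-mode automatic differentiation over numpy arrays.

The cognitive operator family needs only a small closed set of primitives —
grouped convolution, matrix products, GeLU, batch statistics, reshapes and
reductions — so the package carries its own compact tape-based engine rather
than depending on a full deep-learning framework.  Every ``Tensor`` records
its parents and a backward closure; ``Tensor.backward()`` runs the tape in
reverse topological order.  All computation is float64 and fully
deterministic, which the reproducibility contract of the training loop
relies on.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Parameter", "Module", "concat", "conv2d", "gather_rows"]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if parent._backward is None and not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _node(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._backward is not None for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            return [
                (a, _unbroadcast(g, a.data.shape)),
                (b, _unbroadcast(g, b.data.shape)),
            ]

        return self._node(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            return [
                (a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape)),
            ]

        return self._node(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        a = self

        def bw(g):
            return [(a, g * exponent * np.power(a.data, exponent - 1.0))]

        return self._node(np.power(a.data, exponent), (a,), bw)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return [
                (a, _unbroadcast(ga, a.data.shape)),
                (b, _unbroadcast(gb, b.data.shape)),
            ]

        return self._node(a.data @ b.data, (a, b), bw)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bw(g):
            return [(a, g.reshape(old))]

        return self._node(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes) -> "Tensor":
        a = self
        inv = np.argsort(axes)

        def bw(g):
            return [(a, g.transpose(inv))]

        return self._node(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, idx) -> "Tensor":
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            return [(a, full)]

        return self._node(a.data[idx], (a,), bw)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def bw(g):
            if axis is None:
                return [(a, np.broadcast_to(g, a.data.shape).copy())]
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g, axis)
            return [(a, np.broadcast_to(g2, a.data.shape).copy())]

        return self._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ----------------------------------------------------

    def gelu(self) -> "Tensor":
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))

        def bw(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
            return [(a, g * (cdf + x * pdf))]

        return self._node(x * cdf, (a,), bw)

    def exp(self) -> "Tensor":
        a = self
        out = np.exp(a.data)

        def bw(g):
            return [(a, g * out)]

        return self._node(out, (a,), bw)

    def log(self) -> "Tensor":
        a = self

        def bw(g):
            return [(a, g / a.data)]

        return self._node(np.log(a.data), (a,), bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        out = []
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(start, stop)
            out.append((t, g[tuple(idx)]))
        return out

    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad or t._backward is not None for t in tensors):
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Pick ``t[arange(B), idx]`` from a (B, C) tensor."""
    a = Tensor._lift(t)
    idx = np.asarray(idx, dtype=np.int64)
    rows = np.arange(a.data.shape[0])

    def bw(g):
        full = np.zeros_like(a.data)
        full[rows, idx] = g
        return [(a, full)]

    return a._node(a.data[rows, idx], (a,), bw)


# -- convolution -----------------------------------------------------------


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((B, C, k, k, H, W))
    for di in range(k):
        for dj in range(k):
            cols[:, :, di, dj] = xp[:, :, di : di + H, dj : dj + W]
    return cols.reshape(B, C * k * k, H * W)


def _col2im(cols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    B, C, H, W = shape
    cols = cols.reshape(B, C, k, k, H, W)
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
    for di in range(k):
        for dj in range(k):
            xp[:, :, di : di + H, dj : dj + W] += cols[:, :, di, dj]
    return xp[:, :, pad : pad + H, pad : pad + W]


def conv2d(x: Tensor, w: Tensor) -> Tensor:
    """Same-padded stride-1 cross-correlation.

    ``x``: (B, C_in, H, W); ``w``: (C_out, C_in, k, k) with odd ``k``.
    Padding ``k // 2`` keeps the spatial grid, as required for concatenating
    parallel multi-scale branches.
    """
    x = Tensor._lift(x)
    w = Tensor._lift(w)
    B, C, H, W = x.data.shape
    Co, Ci, k, k2 = w.data.shape
    if k != k2 or k % 2 == 0:
        raise ValueError("kernel must be square with odd size")
    if Ci != C:
        raise ValueError(f"kernel expects {Ci} input channels, got {C}")
    pad = k // 2
    cols = _im2col(x.data, k, pad)  # (B, C*k*k, H*W)
    wf = w.data.reshape(Co, C * k * k)
    out_data = (wf @ cols).reshape(B, Co, H, W)

    def bw(g):
        gf = g.reshape(B, Co, H * W)
        gw = np.einsum("boi,bci->oc", gf, cols).reshape(Co, C, k, k)
        gcols = wf.T @ gf  # (B, C*k*k, H*W)
        gx = _col2im(gcols, (B, C, H, W), k, pad)
        return [(x, gx), (w, gw)]

    out = Tensor(out_data)
    if any(t.requires_grad or t._backward is not None for t in (x, w)):
        out._parents = (x, w)
        out._backward = bw
    return out


# -- parameters and modules ------------------------------------------------


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal(shape, rng: np.random.Generator, std: float = 0.02) -> np.ndarray:
    """Truncated-normal init at +-2 std, by resampling."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


class Module:
    """Parameter container with named traversal and train/eval modes."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        def walk(name: str, value):
            if isinstance(value, Parameter):
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(name)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(f"{name}.{i}", item)

        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            yield from walk(full, value)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def _apply_mode(self, training: bool) -> None:
        self.training = training

        def walk(value):
            if isinstance(value, Module):
                value._apply_mode(training)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    walk(item)

        for value in vars(self).values():
            walk(value)

    def train(self) -> "Module":
        self._apply_mode(True)
        return self

    def eval(self) -> "Module":
        self._apply_mode(False)
        return self

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())
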