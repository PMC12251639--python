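"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network in this package is small (~200k parameters) and runs on CPU,
so rather than depending on a deep-learning framework the model is built
on this compact tape-based autograd: a :class:`Tensor` wraps an ndarray
and records a backward closure; :meth:`Tensor.backward` walks the tape in
reverse topological order. Only the operations the model actually needs
are provided (broadcast arithmetic, matmul, dilated same-length 1-d
convolution, GELU/sigmoid, softmax and alpha-entmax with its exact
Jacobian-vector product, slicing, concatenation, L2 normalisation).

Every op's gradient is checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np

from . import sparsecore

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference / evaluation passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        arr = np.asarray(data)
        self.data = arr.astype(np.float32) if arr.dtype != np.float64 else arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name!r})"

    # ------------------------------------------------------------------ tape
    def _track(self) -> bool:
        return _GRAD_ENABLED and self.requires_grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                if node.grad is not None:
                    node._backward(node.grad)
                # free the closure and intermediate grads to bound memory
                node._backward = None
                if not node.requires_grad:
                    node.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return _binop(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binop(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        return _binop(self, other, np.multiply, lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binop(
            self, other, np.divide, lambda g, a, b: (g / b, -g * a / (b * b))
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, exponent: float):
        out = _make(np.power(self.data, exponent), (self,))
        if out._parents:
            x = self.data

            def bw(g):
                _accum(self, g * exponent * np.power(x, exponent - 1.0))

            out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._parents:
            a, b = self.data, other.data

            def bw(g):
                if self._track() or self._parents:
                    _accum(self, g @ b.T)
                if other._track() or other._parents:
                    _accum(other, a.T @ g)

            out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            shape = self.data.shape

            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                _accum(self, np.broadcast_to(g, shape).copy())

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        if out._parents:
            orig = self.data.shape
            out._backward = lambda g: _accum(self, g.reshape(orig))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._parents:
            shape = self.data.shape

            def bw(g):
                full = np.zeros(shape, dtype=g.dtype)
                np.add.at(full, idx, g)
                _accum(self, full)

            out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _needs_graph(*tensors: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad or t._parents for t in tensors)


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    g = _unbroadcast(np.asarray(g), t.data.shape)
    if g.dtype != t.data.dtype:
        g = g.astype(t.data.dtype)  # conversion also breaks aliasing
        fresh = True
    else:
        fresh = False
    if t.grad is None:
        # copy unless already fresh: backward closures may hand the same
        # buffer to several parents (e.g. both arguments of an add)
        t.grad = g if fresh else g.copy()
    else:
        t.grad += g


def _binop(a: Tensor, b, fwd, grads) -> Tensor:
    a = _as_tensor(a)
    b = _as_tensor(b)
    out = _make(fwd(a.data, b.data), (a, b))
    if out._parents:
        ad, bd = a.data, b.data

        def bw(g):
            ga, gb = grads(g, ad, bd)
            if a.requires_grad or a._parents:
                _accum(a, ga)
            if b.requires_grad or b._parents:
                _accum(b, gb)

        out._backward = bw
    return out


# ---------------------------------------------------------------- elementwise
def exp(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = _make(np.exp(x.data), (x,))
    if out._parents:
        y = out.data
        out._backward = lambda g: _accum(x, g * y)
    return out


def log(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = _make(np.log(x.data), (x,))
    if out._parents:
        xd = x.data
        out._backward = lambda g: _accum(x, g / xd)
    return out


def sqrt(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = _make(np.sqrt(x.data), (x,))
    if out._parents:
        y = out.data
        out._backward = lambda g: _accum(x, g * 0.5 / y)
    return out


_GELU_C = math.sqrt(2.0 / math.pi)
_GELU_A = 0.044715


def gelu(x: Tensor) -> Tensor:
    """GELU in its tanh approximation:
    0.5 x (1 + tanh(sqrt(2/pi) (x + 0.044715 x^3))).

    The tanh form is an order of magnitude cheaper than the erf form on
    CPU and agrees with it to ~1e-3, far below training noise.
    """
    x = _as_tensor(x)
    xd = x.data
    x2 = xd * xd
    t = np.tanh(_GELU_C * (xd + _GELU_A * (x2 * xd)))
    out = _make(0.5 * xd * (1.0 + t), (x,))
    if out._parents:

        def bw(g):
            du = _GELU_C * (1.0 + 3.0 * _GELU_A * x2)
            _accum(x, g * (0.5 * (1.0 + t) + 0.5 * xd * (1.0 - t * t) * du))

        out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _make(s, (x,))
    if out._parents:
        out._backward = lambda g: _accum(x, g * s * (1.0 - s))
    return out


# ------------------------------------------------------------- distributions
def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    xd = x.data
    e = np.exp(xd - xd.max(axis=axis, keepdims=True))
    p = e / e.sum(axis=axis, keepdims=True)
    out = _make(p, (x,))
    if out._parents:

        def bw(g):
            dot = np.sum(g * p, axis=axis, keepdims=True)
            _accum(x, (g - dot) * p)

        out._backward = bw
    return out


def entmax(x: Tensor, alpha: float, axis: int = -1) -> Tensor:
    """alpha-entmax with the exact sparse Jacobian in the backward pass."""
    x = _as_tensor(x)
    p = sparsecore.entmax_bisect(x.data, alpha, axis=axis).astype(x.data.dtype)
    out = _make(p, (x,))
    if out._parents:

        def bw(g):
            pm = np.moveaxis(p, axis, -1)
            gm = np.moveaxis(g, axis, -1)
            d = sparsecore.entmax_jvp(None, alpha, pm, gm)
            _accum(x, np.moveaxis(d, -1, axis))

        out._backward = bw
    return out


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Project onto the unit sphere along ``axis`` (epsilon-stabilised)."""
    x = _as_tensor(x)
    norm = np.maximum(np.linalg.norm(x.data, axis=axis, keepdims=True), eps)
    y = x.data / norm
    out = _make(y, (x,))
    if out._parents:

        def bw(g):
            dot = np.sum(g * y, axis=axis, keepdims=True)
            _accum(x, (g - y * dot) / norm)

        out._backward = bw
    return out


def transpose(x: Tensor) -> Tensor:
    """2-d matrix transpose."""
    x = _as_tensor(x)
    out = _make(np.ascontiguousarray(x.data.T), (x,))
    if out._parents:
        out._backward = lambda g: _accum(x, g.T)
    return out


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    _accum(t, piece)

        out._backward = bw
    return out


# -------------------------------------------------------------- convolution
def conv1d_same(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Stride-1, same-length, zero-padded dilated 1-d convolution.

    ``x``: (B, L, C_in) channels-last activations, ``w``: (k, C_in, C_out),
    ``b``: (C_out,). Implemented as im2col + one GEMM; the backward pass
    scatters the column gradient back over the k taps.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    bsz, length, cin = x.data.shape
    k, cin_w, cout = w.data.shape
    if cin_w != cin:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    pad_total = (k - 1) * dilation
    pl = pad_total // 2
    pr = pad_total - pl
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    if k == 1:
        cols = xp.reshape(bsz * length, cin)
    else:
        cols = np.stack(
            [xp[:, j * dilation : j * dilation + length, :] for j in range(k)],
            axis=2,
        ).reshape(bsz * length, k * cin)
    wmat = w.data.reshape(k * cin, cout)
    y = (cols @ wmat + b.data).reshape(bsz, length, cout)
    out = _make(y, (x, w, b))
    if out._parents:

        def bw(g):
            g2 = g.reshape(bsz * length, cout)
            if w.requires_grad or w._parents:
                _accum(w, (cols.T @ g2).reshape(k, cin, cout))
            if b.requires_grad or b._parents:
                _accum(b, g2.sum(axis=0))
            if x.requires_grad or x._parents:
                dcols = (g2 @ wmat.T).reshape(bsz, length, k, cin)
                dxp = np.zeros_like(xp)
                for j in range(k):
                    dxp[:, j * dilation : j * dilation + length, :] += dcols[:, :, j, :]
                _accum(x, dxp[:, pl : pl + length, :])

        out._backward = bw
    return out


# ----------------------------------------------------------------- optimiser
class Parameter(Tensor):
    __slots__ = ("tag",)

    def __init__(self, data, name: str = "", tag: str = ""):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True, name=name)
        self.tag = tag


class AdamW:
    """AdamW with per-parameter learning-rate multipliers and freezing.

    ``trainable_tags`` and ``lr_scales`` are reset by the curriculum at
    each phase boundary; frozen parameters keep their moment estimates.
    """

    def __init__(self, params: list[Parameter], betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0
        self.trainable_tags: set[str] | None = None
        self.lr_scales: dict[str, float] = {}

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float, weight_decay: float = 0.0, clip_norm: float | None = 5.0) -> None:
        active = [
            (i, p)
            for i, p in enumerate(self.params)
            if p.grad is not None
            and (self.trainable_tags is None or p.tag in self.trainable_tags)
        ]
        if not active:
            return
        if clip_norm is not None:
            total = math.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2)) for _, p in active))
            if total > clip_norm:
                scale = clip_norm / (total + 1e-12)
                for _, p in active:
                    p.grad *= scale
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in active:
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            plr = lr * self.lr_scales.get(p.tag, 1.0)
            p.data -= plr * (mhat / (np.sqrt(vhat) + self.eps) + weight_decay * p.data)
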