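"""Reverse-mode automatic differentiation on numpy arrays.

A minimal define-by-run tape: every operation returns a new :class:`Tensor`
holding the forward value and a closure that propagates the adjoint to its
inputs.  Only the operations needed by the convolution/attention models in
this package are provided; all of them are vectorized (the convolution loops
run over the kernel window, never over pixels).

Gradients are accumulated in ``float`` arrays of the same dtype as the data.
Graph construction can be suspended with :func:`no_grad` for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _tracing(*tensors: "Tensor") -> bool:
    return _GRAD_ENABLED and any(t.requires_grad for t in tensors)


class Tensor:
    """An n-dimensional array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind in "iub":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- book-keeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, power(_as_tensor(other), -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _make(data: np.ndarray, parents: Sequence[Tensor], backward: Callable[[Tensor], Callable[[], None]]) -> Tensor:
    out = Tensor(data)
    if _tracing(*parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward(out)
    return out


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad, b.shape))
        return run

    return _make(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad * a.data, b.shape))
        return run

    return _make(data, (a, b), bw)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** p

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * p * a.data ** (p - 1))
        return run

    return _make(data, (a,), bw)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * out.data)
        return run

    return _make(data, (a,), bw)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad / a.data)
        return run

    return _make(data, (a,), bw)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(out):
        def run():
            if not a.requires_grad:
                return
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())
        return run

    return _make(data, (a,), bw)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.size if axis is None else np.prod([a.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def relu(a) -> Tensor:
    a = _as_tensor(a)
    data = np.maximum(a.data, 0)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * (a.data > 0))
        return run

    return _make(data, (a,), bw)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * out.data * (1.0 - out.data))
        return run

    return _make(data, (a,), bw)


def silu(a) -> Tensor:
    """x * sigmoid(x) (a.k.a. swish)."""
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    data = a.data * s

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * (s + a.data * s * (1.0 - s)))
        return run

    return _make(data, (a,), bw)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def bw(out):
        def run():
            if a.requires_grad:
                y, g = out.data, out.grad
                a._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))
        return run

    return _make(data, (a,), bw)


# ---------------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad.reshape(a.shape))
        return run

    return _make(data, (a,), bw)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad.transpose(inv))
        return run

    return _make(data, (a,), bw)


def pad2d(a, pad) -> Tensor:
    """Zero-pad the last two axes; ``pad`` is an int (symmetric) or a
    (top, bottom, left, right) tuple."""
    a = _as_tensor(a)
    if isinstance(pad, int):
        pad = (pad, pad, pad, pad)
    t, b_, l, r = pad
    if not any(pad):
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(t, b_), (l, r)]
    data = np.pad(a.data, width)
    H, W = a.shape[-2], a.shape[-1]

    def bw(out):
        def run():
            if a.requires_grad:
                sl = (Ellipsis, slice(t, t + H), slice(l, l + W))
                a._accumulate(out.grad[sl])
        return run

    return _make(data, (a,), bw)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    """a @ b with ``b`` of rank 2; ``a`` may carry leading batch axes."""
    a, b = _as_tensor(a), _as_tensor(b)
    if b.ndim != 2:
        raise ValueError("matmul: right operand must be a matrix")
    data = a.data @ b.data

    def bw(out):
        def run():
            g = out.grad
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                gb = np.tensordot(a.data, g, axes=(tuple(range(a.ndim - 1)),
                                                   tuple(range(g.ndim - 1))))
                b._accumulate(gb)
        return run

    return _make(data, (a, b), bw)


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, grouped.

    ``w`` has shape (C_out, C_in/groups, kh, kw).  Implemented as a loop over
    the (kh, kw) kernel window with einsum over channels, which is fast for
    the 1x1 and 3x3 kernels used here.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    N, C, H, W = x.shape
    Co, Cig, kh, kw = w.shape
    G = groups
    if C != Cig * G or Co % G:
        raise ValueError(f"conv2d: channel/group mismatch ({C=}, {w.shape=}, {G=})")
    Cog = Co // G
    s = stride
    Hp, Wp = H + 2 * padding, W + 2 * padding
    Ho, Wo = (Hp - kh) // s + 1, (Wp - kw) // s + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("conv2d: output would be empty")

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    xg = xp.reshape(N, G, Cig, Hp, Wp)
    wg = w.data.reshape(G, Cog, Cig, kh, kw)
    out = np.zeros((N, G, Cog, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            patch = xg[:, :, :, i:i + s * Ho:s, j:j + s * Wo:s]
            out += np.einsum("goc,ngchw->ngohw", wg[:, :, :, i, j], patch, optimize=True)
    data = out.reshape(N, Co, Ho, Wo)
    if b is not None:
        data = data + b.data.reshape(1, Co, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(outT):
        def run():
            g = outT.grad.reshape(N, G, Cog, Ho, Wo)
            if b is not None and b.requires_grad:
                b._accumulate(outT.grad.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                dw = np.zeros_like(wg)
                for i in range(kh):
                    for j in range(kw):
                        patch = xg[:, :, :, i:i + s * Ho:s, j:j + s * Wo:s]
                        dw[:, :, :, i, j] = np.einsum("ngohw,ngchw->goc", g, patch,
                                                      optimize=True)
                w._accumulate(dw.reshape(w.shape))
            if x.requires_grad:
                dxp = np.zeros((N, G, Cig, Hp, Wp), dtype=x.dtype)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, :, i:i + s * Ho:s, j:j + s * Wo:s] += np.einsum(
                            "goc,ngohw->ngchw", wg[:, :, :, i, j], g, optimize=True)
                dx = dxp.reshape(N, C, Hp, Wp)
                if padding:
                    dx = dx[:, :, padding:-padding, padding:-padding]
                x._accumulate(dx)
        return run

    return _make(data, parents, bw)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def batch_norm(x, gamma, beta, running_mean, running_var, *, training: bool,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) of an NCHW tensor.

    ``running_mean``/``running_var`` are plain arrays updated in place during
    training (outside the tape).
    """
    x = _as_tensor(x)
    C = x.shape[1]
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) * ivar.reshape(1, C, 1, 1)
    data = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def bw(out):
        def run():
            g = out.grad
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                gi = gamma.data.reshape(1, C, 1, 1) * ivar.reshape(1, C, 1, 1)
                if training:
                    M = x.shape[0] * x.shape[2] * x.shape[3]
                    gsum = g.sum(axis=axes, keepdims=True)
                    gx = (g * xhat).sum(axis=axes, keepdims=True)
                    x._accumulate(gi / M * (M * g - gsum - xhat * gx))
                else:
                    x._accumulate(gi * g)
        return run

    return _make(data, (x, gamma, beta), bw)


def layer_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    x = _as_tensor(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    data = gamma.data * xhat + beta.data

    def bw(out):
        def run():
            g = out.grad
            red = tuple(range(x.ndim - 1))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=red))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=red))
            if x.requires_grad:
                D = x.shape[-1]
                gh = g * gamma.data
                gsum = gh.sum(axis=-1, keepdims=True)
                gx = (gh * xhat).sum(axis=-1, keepdims=True)
                x._accumulate(ivar / D * (D * gh - gsum - xhat * gx))
        return run

    return _make(data, (x, gamma, beta), bw)


# ---------------------------------------------------------------------------
# losses and quantization
# ---------------------------------------------------------------------------

def cross_entropy(logits, labels) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer class labels."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    N, C = logits.shape
    if labels.min() < 0 or labels.max() >= C:
        raise ValueError("cross_entropy: label out of range")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    data = -logp[np.arange(N), labels].mean()

    def bw(out):
        def run():
            if logits.requires_grad:
                p = np.exp(logp)
                p[np.arange(N), labels] -= 1.0
                logits._accumulate(out.grad * p / N)
        return run

    return _make(np.asarray(data, dtype=logits.dtype), (logits,), bw)


def fake_quantize(x, scale: np.ndarray, zero_point: np.ndarray,
                  qmin: int, qmax: int) -> Tensor:
    """Quantize-dequantize with a straight-through gradient.

    The backward pass passes the adjoint through unchanged wherever the input
    falls inside the representable range and zeroes it where the clamp was
    active (the standard STE-with-clipping rule).
    """
    x = _as_tensor(x)
    scale = np.asarray(scale, dtype=np.float64)
    zero_point = np.asarray(zero_point)
    # double-precision intermediate so a very wide bitwidth degenerates to a
    # true identity (no float32 divide/multiply round-trip noise)
    q = np.clip(np.round(x.data.astype(np.float64) / scale) + zero_point, qmin, qmax)
    data = ((q - zero_point) * scale).astype(x.dtype)
    inside = None
    if _tracing(x):
        lo = (qmin - zero_point) * scale
        hi = (qmax - zero_point) * scale
        inside = (x.data >= lo) & (x.data <= hi)

    def bw(out):
        def run():
            if x.requires_grad:
                x._accumulate(out.grad * inside)
        return run

    return _make(data.astype(x.dtype), (x,), bw)


def numeric_gradient(f: Callable[[np.ndarray], float], x: np.ndarray,
                     eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient, for gradient-checking tests."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
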