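"""Separable self-attention (the linear-complexity MobileViTv2 attention).

Instead of a k x k token-affinity matrix, each token receives a scalar
context score; the softmax-normalized scores weight the key branch into a
single global context vector cv, which is broadcast back over the
ReLU-activated value branch:

    cs  = softmax(x W_I)                 (scores, one per token)
    cv  = sum_i cs_i * (x W_K)_i         (global context, in R^d)
    y_i = (cv * ReLU((x W_V)_i)) W_O     (broadcast elementwise product)

Cost is linear in the token count k (no quadratic attention matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor
from ..nn.modules import MacRecorder, Module, Parameter


@dataclass
class AttentionParams:
    """Raw projection weights for a functional attention evaluation.

    ``w_i``: (d, 1) score projection; ``w_k``, ``w_v``, ``w_o``: (d, d).
    """

    w_i: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    w_o: np.ndarray

    @classmethod
    def random(cls, d: int, rng: np.random.Generator) -> "AttentionParams":
        s = 1.0 / np.sqrt(d)
        return cls(rng.normal(0, s, (d, 1)), rng.normal(0, s, (d, d)),
                   rng.normal(0, s, (d, d)), rng.normal(0, s, (d, d)))


def separable_self_attention(x: Tensor | np.ndarray, p: AttentionParams) -> Tensor:
    """Apply separable self-attention to a (..., k, d) token matrix."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("non-finite input tokens")
    d = x.shape[-1]
    if p.w_i.shape != (d, 1) or p.w_k.shape != (d, d):
        raise ValueError("projection shapes inconsistent with token width")
    k_axis = x.ndim - 2
    scores = ag.matmul(x, Tensor(p.w_i))                      # (..., k, 1)
    cs = ag.softmax(scores, axis=k_axis)
    xk = ag.matmul(x, Tensor(p.w_k))
    cv = ag.sum_(ag.mul(cs, xk), axis=k_axis, keepdims=True)  # (..., 1, d)
    xv = ag.relu(ag.matmul(x, Tensor(p.w_v)))
    y = ag.matmul(ag.mul(cv, xv), Tensor(p.w_o))
    return y


def context_scores(x: np.ndarray, p: AttentionParams) -> np.ndarray:
    """The normalized score simplex over tokens (diagnostic helper)."""
    z = x @ p.w_i
    z = z - z.max(axis=-2, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=-2, keepdims=True))[..., 0]


class SeparableSelfAttention(Module):
    """Module form with trainable projections (optionally biased)."""

    def __init__(self, dim: int, *, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        s = 1.0 / np.sqrt(dim)
        self.dim = dim
        self.w_i = Parameter(rng.normal(0, s, (dim, 1)))
        self.w_k = Parameter(rng.normal(0, s, (dim, dim)))
        self.w_v = Parameter(rng.normal(0, s, (dim, dim)))
        self.w_o = Parameter(rng.normal(0, s, (dim, dim)))
        self.b_k = Parameter(np.zeros(dim))
        self.b_v = Parameter(np.zeros(dim))
        self.b_o = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        d = self.dim
        k_axis = x.ndim - 2
        k = x.shape[k_axis]
        groups = int(np.prod(x.shape[:k_axis])) if k_axis else 1
        # no score bias: softmax is invariant to a constant shift
        cs = ag.softmax(ag.matmul(x, self.w_i), axis=k_axis)
        xk = ag.add(ag.matmul(x, self.w_k), self.b_k)
        cv = ag.sum_(ag.mul(cs, xk), axis=k_axis, keepdims=True)
        xv = ag.relu(ag.add(ag.matmul(x, self.w_v), self.b_v))
        y = ag.add(ag.matmul(ag.mul(cv, xv), self.w_o), self.b_o)
        # per token group: k*d (scores) + 2*k*d^2 (K, V) + k*d (context sum)
        # + k*d (broadcast product) + k*d^2 (W_O)
        MacRecorder.record("separable_attention",
                           groups * (3 * k * d + 3 * k * d * d))
        return y
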