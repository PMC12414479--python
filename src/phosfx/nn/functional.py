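"""Standalone differentiable ops exposed by name.

These are the equation-level primitives of the models; each accepts
numpy arrays or Tensors and returns a Tensor (use ``.data`` for the
plain array).
"""

from __future__ import annotations

import numpy as np

from .layers import scaled_dot_attention
from .tensor import Tensor, as_tensor, softmax


def gelu(x) -> Tensor:
    """Gaussian error linear unit, x * Phi(x), with the exact erf form
    (not the tanh approximation)."""
    x = as_tensor(x)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("gelu: non-finite input")
    return x.gelu()


def glu(x, w1, b1, w2, b2) -> Tensor:
    """Gated linear unit: (X W1 + b1) elementwise-times sigmoid(X W2 + b2)."""
    x = as_tensor(x)
    return (x @ as_tensor(w1) + as_tensor(b1)) * (x @ as_tensor(w2) + as_tensor(b2)).sigmoid()


def attention(q, k, v, mask: np.ndarray | None = None) -> Tensor:
    """Scaled dot-product attention softmax(Q K^T / sqrt(d_k)) V.

    ``q``: (..., Lq, d_k); ``k``: (..., Lk, d_k); ``v``: (..., Lk, d_v).
    ``mask``: boolean over key positions (True = attend); raising if every
    key of some query row is masked.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(
            f"attention: query dim {q.shape[-1]} != key dim {k.shape[-1]}"
        )
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("attention: key and value row counts differ")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("attention: all keys masked")
        mask = mask.reshape((1,) * (q.ndim - 1) + (k.shape[-2],)) if mask.ndim == 1 else mask
    return scaled_dot_attention(q, k, v, mask=mask)


def attention_weights(q, k, mask: np.ndarray | None = None) -> np.ndarray:
    """The softmax weight matrix of :func:`attention` (no gradient)."""
    q, k = as_tensor(q), as_tensor(k)
    scores = (q @ k.T) * (1.0 / np.sqrt(q.shape[-1]))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
    return softmax(Tensor(scores.data), axis=-1, mask=mask).data
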