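"""Neural building blocks: linear/conv layers, norms, multi-head attention.

All layers operate on single-sample tensors (no batch axis): sequences are
``(L, D)`` matrices and feature vectors are ``(1, D)``. Minibatching is
done by the training loop, which averages per-sample losses.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv1d_same, softmax


class Module:
    """Base class: recursive named-parameter collection."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.parameters(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{i}"] = item
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def reset_cache(self) -> None:
        """Drop any memoised forward results (models that share per-protein
        computations across samples override this; caches must be cleared
        whenever parameters change)."""

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {k}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_xavier(rng, in_dim, out_dim, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution over sequence rows with same-length zero padding.

    Input ``(L, C_in)`` -> output ``(L, C_out)``. Kernel size must be odd
    so the receptive field is centred on each position.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd for centred same-padding")
        self.kernel_size = kernel_size
        fan_in = in_ch * kernel_size
        self.weight = Tensor(
            _xavier(rng, fan_in, out_ch, (kernel_size, in_ch, out_ch)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.weight, self.bias)


class LayerNorm(Module):
    """Normalisation over the last (feature) axis with learned affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.standardize(eps=self.eps) * self.gain + self.shift


class GroupNorm(Module):
    """Group normalisation for a single feature vector of width C.

    Channels are split into ``groups`` contiguous groups; each group is
    standardised independently before the learned affine.
    """

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups != 0:
            raise ValueError("channels must be divisible by groups")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gain = Tensor(np.ones(channels), requires_grad=True)
        self.shift = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[-1]}")
        grouped = x.reshape(-1, self.groups, self.channels // self.groups)
        normed = grouped.standardize(eps=self.eps).reshape(*x.shape)
        return normed * self.gain + self.shift


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product attention (query, memory) -> query-shaped.

    ``key_mask`` is a boolean vector over memory rows (True = attend);
    masked rows receive zero attention weight.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError("model dim must be divisible by the number of heads")
        self.dim = dim
        self.heads = heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def project_kv(self, memory: Tensor) -> tuple[Tensor, Tensor]:
        """Per-head key/value projections of a memory matrix, (H, L, dk).

        Row-wise, so the projections of a concatenated memory equal the
        concatenation of the per-part projections — callers may cache
        them per part and concatenate along axis 1.
        """
        Lk = memory.shape[0]
        dk = self.dim // self.heads
        k = self.k_proj(memory).reshape(Lk, self.heads, dk).transpose(1, 0, 2)
        v = self.v_proj(memory).reshape(Lk, self.heads, dk).transpose(1, 0, 2)
        return k, v

    def attend(
        self,
        query: Tensor,
        kv: tuple[Tensor, Tensor],
        key_mask: np.ndarray | None = None,
    ) -> Tensor:
        k, v = kv
        Lq, Lk = query.shape[0], k.shape[1]
        dk = self.dim // self.heads
        q = self.q_proj(query).reshape(Lq, self.heads, dk).transpose(1, 0, 2)
        mask = None if key_mask is None else np.asarray(key_mask, bool).reshape(1, 1, Lk)
        out = scaled_dot_attention(q, k, v, mask=mask)
        return self.out_proj(out.transpose(1, 0, 2).reshape(Lq, self.dim))

    def attend_batched(
        self,
        query: Tensor,
        kv: tuple[Tensor, Tensor],
        key_mask: np.ndarray | None = None,
    ) -> Tensor:
        """Batched attention: ``query`` (B, Lq, dim); K/V (B, H, Lk, dk);
        ``key_mask`` boolean (B, Lk)."""
        k, v = kv
        B, Lq = query.shape[0], query.shape[1]
        Lk = k.shape[2]
        dk = self.dim // self.heads
        q = self.q_proj(query).reshape(B, Lq, self.heads, dk).transpose(0, 2, 1, 3)
        mask = (
            None
            if key_mask is None
            else np.asarray(key_mask, bool).reshape(B, 1, 1, Lk)
        )
        out = scaled_dot_attention(q, k, v, mask=mask)
        return self.out_proj(out.transpose(0, 2, 1, 3).reshape(B, Lq, self.dim))

    def project_kv_batched(self, memory: Tensor) -> tuple[Tensor, Tensor]:
        """K/V for a batched memory (B, Lk, dim) -> (B, H, Lk, dk) each."""
        B, Lk = memory.shape[0], memory.shape[1]
        dk = self.dim // self.heads
        k = self.k_proj(memory).reshape(B, Lk, self.heads, dk).transpose(0, 2, 1, 3)
        v = self.v_proj(memory).reshape(B, Lk, self.heads, dk).transpose(0, 2, 1, 3)
        return k, v

    def __call__(self, query: Tensor, memory: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        return self.attend(query, self.project_kv(memory), key_mask=key_mask)


def scaled_dot_attention(
    q: Tensor, k: Tensor, v: Tensor, mask: np.ndarray | None = None
) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V, batched over any leading axes.

    ``mask`` is boolean over key positions (broadcastable to the score
    shape); all-masked rows raise.
    """
    dk = q.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (1.0 / np.sqrt(dk))
    weights = softmax(scores, axis=-1, mask=mask)
    return weights @ v


class FeedForward(Module):
    """Position-wise two-layer network with GELU."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())
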