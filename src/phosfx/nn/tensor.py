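"""A small reverse-mode automatic-differentiation engine over numpy arrays.

This is the numerical substrate for the neural models in this package.
Arrays are float64 throughout; graphs are built eagerly and freed after
``backward``. The op set is exactly what the models need: broadcasted
arithmetic, (batched) matmul, reductions, elementwise nonlinearities,
shape ops, padding/slicing for convolutions, and a numerically stable
softmax.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # collapse axes that were broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
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
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data)
            if grad is None
            else np.asarray(grad, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bwd
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = _bwd
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        assert np.isscalar(exponent)
        out = Tensor(self.data**exponent, _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = _bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        a, b = self.data, other.data
        out = Tensor(a @ b, _prev=(self, other))

        def _bwd(g):
            if self.requires_grad:
                ga = g @ b.swapaxes(-1, -2)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = a.swapaxes(-1, -2) @ g
                other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = _bwd
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise -------------------------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = _bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _bwd
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    def sigmoid(self) -> "Tensor":
        s = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic
        out = Tensor(s, _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = _bwd
        return out

    def gelu(self) -> "Tensor":
        """Exact GELU x * Phi(x) with Phi from the Gaussian error function."""
        phi = 0.5 * (1.0 + _erf(self.data * _INV_SQRT2))
        out = Tensor(self.data * phi, _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                density = _INV_SQRT2PI * np.exp(-0.5 * self.data**2)
                self._accumulate(g * (phi + self.data * density))

        out._backward = _bwd
        return out

    def standardize(self, eps: float = 1e-5) -> "Tensor":
        """Fused per-row standardisation over the last axis:
        (x - mean) / sqrt(var + eps), with the analytic gradient."""
        mu = self.data.mean(axis=-1, keepdims=True)
        centred = self.data - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = centred * inv
        out = Tensor(y, _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                gm = g.mean(axis=-1, keepdims=True)
                gym = (g * y).mean(axis=-1, keepdims=True)
                self._accumulate(inv * (g - gm - y * gym))

        out._backward = _bwd
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = _bwd
        return out

    def transpose(self, *axes) -> "Tensor":
        axes = axes or tuple(reversed(range(self.data.ndim)))
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = _bwd
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, index) -> "Tensor":
        out = Tensor(self.data[index], _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[index] = g
                self._accumulate(full)

        out._backward = _bwd
        return out

    def pad_rows(self, before: int, after: int) -> "Tensor":
        """Zero-pad along axis 0 (rows); used for same-length convolutions."""
        width = [(before, after)] + [(0, 0)] * (self.data.ndim - 1)
        out = Tensor(np.pad(self.data, width), _prev=(self,))
        n = self.data.shape[0]

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g[before : before + n])

        out._backward = _bwd
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = _bwd
    return out


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Stable softmax along ``axis``, fused with its analytic gradient.

    ``mask`` (broadcastable boolean array, True = keep) removes positions
    from the normalisation; rows sum to 1 over the kept positions, which
    receive exactly zero weight.
    """
    x = as_tensor(x)
    z = x.data
    if mask is not None:
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), z.shape)
        if not mask.any(axis=axis).all():
            raise ValueError("softmax: at least one row has all positions masked")
        z = np.where(mask, z, -np.inf)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _prev=(x,))

    def _bwd(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

    out._backward = _bwd
    return out


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Fused same-length 1-D convolution over rows.

    ``x``: (L, C_in); ``weight``: (k, C_in, C_out) with odd k; ``bias``:
    (C_out,). Implemented as an im2col matmul with an analytic gradient.
    """
    k, c_in, c_out = weight.shape
    half = k // 2
    L = x.shape[0]
    xp = np.pad(x.data, ((half, half), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (k, c_in)).reshape(L, k * c_in)
    w2 = weight.data.reshape(k * c_in, c_out)
    out = Tensor(cols @ w2 + bias.data, _prev=(x, weight, bias))

    def _bwd(g):
        if weight.requires_grad:
            weight._accumulate((cols.T @ g).reshape(k, c_in, c_out))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=0))
        if x.requires_grad:
            gcols = (g @ w2.T).reshape(L, k, c_in)
            gxp = np.zeros_like(xp)
            for o in range(k):
                gxp[o : o + L] += gcols[:, o, :]
            x._accumulate(gxp[half : half + L])

    out._backward = _bwd
    return out


def parameters_vector(params: Iterable[Tensor]) -> np.ndarray:
    """Flatten parameter values into one vector (finite-difference checks)."""
    return np.concatenate([p.data.ravel() for p in params])
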