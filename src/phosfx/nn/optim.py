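"""Optimizers: rectified Adam (RAdam) and the Lookahead wrapper.

RAdam rectifies Adam's adaptive learning rate in the early steps, when
the variance estimate is unreliable: while the rectification term is
undefined (few effective samples) it falls back to an unadapted momentum
step. Lookahead keeps a slow copy of the weights and every ``k`` inner
steps interpolates slow -> fast by ``alpha``, then restarts the fast
weights from the slow ones.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class RAdam:
    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 5e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = dict(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.rho_inf = 2.0 / (1.0 - self.beta2) - 1.0

    def step(self) -> None:
        self.t += 1
        t = self.t
        beta2_t = self.beta2**t
        rho_t = self.rho_inf - 2.0 * t * beta2_t / (1.0 - beta2_t)
        bias1 = 1.0 - self.beta1**t
        for key, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self.m[key]
            v = self.v[key]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            m_hat = m / bias1
            if rho_t > 4.0:
                r_num = (rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf
                r_den = (self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t
                rect = np.sqrt(r_num / r_den)
                v_hat = np.sqrt(v / (1.0 - beta2_t)) + self.eps
                p.data = p.data - self.lr * rect * m_hat / v_hat
            else:
                p.data = p.data - self.lr * m_hat

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


class Lookahead:
    """Wraps an inner optimizer; synchronises slow weights every k steps."""

    def __init__(self, inner: RAdam, k: int = 5, alpha: float = 0.5):
        if k < 1:
            raise ValueError("lookahead k must be >= 1")
        if not 0.0 < alpha <= 1.0:
            raise ValueError("lookahead alpha must be in (0, 1]")
        self.inner = inner
        self.k = k
        self.alpha = alpha
        self._step_count = 0
        self.slow = {key: p.data.copy() for key, p in inner.params.items()}

    def step(self) -> None:
        self.inner.step()
        self._step_count += 1
        if self._step_count % self.k == 0:
            for key, p in self.inner.params.items():
                slow = self.slow[key]
                slow += self.alpha * (p.data - slow)
                p.data = slow.copy()

    def zero_grad(self) -> None:
        self.inner.zero_grad()
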