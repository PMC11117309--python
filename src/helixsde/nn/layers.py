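"""Building blocks for the score network: seeded parameter initialization,
dense layers, Gaussian Fourier time features and a plain Adam optimizer."""
from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Linear", "fourier_features", "Adam"]


class Linear:
    """Dense layer y = x @ W + b acting on the last axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


def fourier_features(log_sigma: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Gaussian Fourier embedding of log(sigma): [sin(f_i s), cos(f_i s)].

    ``freqs`` are fixed (non-trainable) random frequencies; returns
    (B, 2 * len(freqs)) float32.
    """
    arg = np.asarray(log_sigma, dtype=np.float32)[:, None] * freqs[None, :]
    return np.concatenate([np.sin(arg), np.cos(arg)], axis=1).astype(np.float32)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
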