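"""Noise-conditional score network for helix feature maps.

A compact multiscale encoder-decoder over the L x F map: residue-wise
encoding, a downsampled (L/2) stage with single-head self-attention so every
residue can see the whole helix, then upsampling with a skip connection back
to full resolution. Noise conditioning enters as a Gaussian Fourier embedding
of log(sigma) added at each stage.

The raw network F is wrapped in denoiser preconditioning centered on the
per-entry data mean mu with per-entry data scale s (both estimated from the
training set):

    x0_hat = mu + c_skip * (x - mu) + c_out * F(c_in * (x - mu), sigma)
    c_in   = 1 / sqrt(sigma^2 + s^2)
    c_skip = s^2 / (sigma^2 + s^2)
    c_out  = sigma * s / sqrt(sigma^2 + s^2)

so the denoised estimate interpolates between the noisy input (small sigma)
and a pure network prediction (large sigma), stays bounded for states far
off the data manifold, and collapses exactly to 0 for constant-zero channels
(mask-padded angle slots, where s = 0). The exposed prediction is
``eps_hat = (x0_hat - x) / sigma``; the score is ``eps_hat / sigma``.

Everything is float32 numpy via :mod:`helixsde.nn.autodiff`; evaluation is
deterministic given fixed parameters.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .layers import Linear, fourier_features

__all__ = ["ScoreNet"]


class ScoreNet:
    def __init__(
        self,
        length: int = 14,
        n_features: int = 30,
        width: int = 96,
        width_mid: int = 128,
        t_dim: int = 64,
        seed: int = 0,
    ):
        if length % 2 != 0:
            raise ValueError("length must be even (one 2x pooling stage)")
        self.config = dict(
            length=length, n_features=n_features, width=width,
            width_mid=width_mid, t_dim=t_dim, seed=seed,
        )
        self.L, self.F = length, n_features
        # per-entry data mean/scale for preconditioning; set from the
        # training set by train(); 0.25 is the order of one-hot columns
        self.sigma_data = np.full((length, n_features), 0.25, dtype=np.float32)
        self.x_mean = np.zeros((length, n_features), dtype=np.float32)
        # per-entry circular re-cut applied to angle channels before the
        # model sees the data (wrap moved to the lowest-density angle)
        self.x_shift = np.zeros((length, n_features), dtype=np.float32)
        w, wm = width, width_mid
        rng = np.random.default_rng(seed)
        self.freqs = (rng.standard_normal(t_dim // 2) * 1.0).astype(np.float32)
        self.t1 = Linear(t_dim, t_dim, rng)
        self.t2 = Linear(t_dim, t_dim, rng)
        self.enc1 = Linear(n_features, w, rng)
        self.tp1 = Linear(t_dim, w, rng)
        self.enc2 = Linear(w, w, rng)
        self.down = Linear(w, wm, rng)
        self.tp2 = Linear(t_dim, wm, rng)
        self.wq = Linear(wm, wm, rng)
        self.wk = Linear(wm, wm, rng)
        self.wv = Linear(wm, wm, rng)
        self.attn_out = Linear(wm, wm, rng)
        self.mid = Linear(wm, wm, rng)
        self.tpm = Linear(t_dim, wm, rng)
        self.dec1 = Linear(wm + w, w, rng)
        self.tp3 = Linear(t_dim, w, rng)
        self.dec2 = Linear(w, n_features, rng, zero_init=True)
        self._layers = [
            self.t1, self.t2, self.enc1, self.tp1, self.enc2, self.down,
            self.tp2, self.wq, self.wk, self.wv, self.attn_out, self.mid,
            self.tpm, self.dec1, self.tp3, self.dec2,
        ]

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self._layers for p in layer.params]

    def forward(self, x: np.ndarray, sigma: np.ndarray) -> Tensor:
        """Predict eps_hat = (x0_hat - x) / sigma for a batch.

        x: (B, L, F); sigma: (B,). Returns an autodiff Tensor.
        """
        x = np.asarray(x, dtype=np.float32)
        sigma = np.asarray(sigma, dtype=np.float32).reshape(-1)
        B = x.shape[0]
        s = self.sigma_data[None, :, :]
        mu = self.x_mean[None, :, :]
        sg = sigma[:, None, None]
        c2 = sg**2 + s**2
        c_in = 1.0 / np.sqrt(c2)
        c_skip = s**2 / c2
        c_out = sg * s / np.sqrt(c2)
        xc = x - mu
        xin = Tensor(c_in * xc)
        te = Tensor(fourier_features(np.log(sigma), self.freqs))
        te = self.t2(self.t1(te).silu()).silu()  # (B, t_dim)

        h = (self.enc1(xin) + self.tp1(te).reshape(B, 1, -1)).silu()
        h = self.enc2(h).silu()                            # (B, L, w)
        hd = h.reshape(B, self.L // 2, 2, h.shape[-1]).mean(axis=2)
        hd = (self.down(hd) + self.tp2(te).reshape(B, 1, -1)).silu()  # (B, L/2, wm)
        q, k, v = self.wq(hd), self.wk(hd), self.wv(hd)
        att = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(q.shape[-1]))
        hd = hd + self.attn_out(att.softmax(axis=-1) @ v)
        hd = hd + (self.mid(hd) + self.tpm(te).reshape(B, 1, -1)).silu()
        hu = hd.repeat(2, axis=1)                          # (B, L, wm)
        hu = concat([hu, h], axis=-1)
        hu = (self.dec1(hu) + self.tp3(te).reshape(B, 1, -1)).silu()
        F = self.dec2(hu)                                  # (B, L, F)
        # eps_hat = (x0_hat - x)/sigma
        #         = (c_skip - 1)/sigma * (x - mu) + c_out/sigma * F
        return Tensor((c_skip - 1.0) / sg * xc) + Tensor(c_out / sg) * F

    def eps(self, x: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """Deterministic eps_hat evaluation (no gradient graph kept)."""
        return self.forward(x, sigma).data

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        arrays["freqs"] = self.freqs
        arrays["sigma_data"] = self.sigma_data
        arrays["x_mean"] = self.x_mean
        arrays["x_shift"] = self.x_shift
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.config, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ScoreNet":
        path = Path(path)
        config = json.loads(path.with_suffix(".json").read_text())
        keys = ("length", "n_features", "width", "width_mid", "t_dim", "seed")
        net = cls(**{k: config[k] for k in keys})
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(net.params):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = arr.astype(np.float32)
        net.freqs = data["freqs"].astype(np.float32)
        net.sigma_data = data["sigma_data"].astype(np.float32)
        net.x_mean = data["x_mean"].astype(np.float32)
        net.x_shift = data["x_shift"].astype(np.float32)
        return net
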