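"""Variance-exploding SDE diffusion: forward perturbation kernel, denoising
score matching, and predictor-corrector reverse-time sampling.

The forward process has zero drift and a geometrically growing noise scale

    sigma(t) = sigma_min * (sigma_max / sigma_min) ** t,   t in [0, 1],

so the perturbation kernel is simply x_t = x_0 + sigma(t) * z with z standard
normal. The reverse-time SDE is integrated with an Euler-Maruyama predictor
followed by Langevin MCMC corrector steps whose step size is set from a
signal-to-noise ratio r: eps = 2 * (r * ||z|| / ||s||)^2.

A trained :class:`ScoreModel` wraps the neural eps-predictor
(:class:`helixsde.nn.ScoreNet`); the score is eps_hat(x, sigma(t)) / sigma(t).
All sampling entry points also accept a plain callable ``score(x, t)`` so the
sampler can be validated against analytic scores with no training involved.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .featuremap import HelixFeatureMap
from .nn import Adam, ScoreNet, Tensor

__all__ = [
    "VESDEParams",
    "SamplerConfig",
    "ScoreModel",
    "sigma",
    "perturb",
    "dsm_loss",
    "train",
    "pc_sample",
    "sample_feature_maps",
]


@dataclass(frozen=True)
class VESDEParams:
    sigma_min: float = 0.01
    sigma_max: float = 50.0
    n_steps: int = 1000

    def __post_init__(self):
        if not 0 < self.sigma_min < self.sigma_max:
            raise ValueError("need 0 < sigma_min < sigma_max")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


@dataclass(frozen=True)
class SamplerConfig:
    n_steps: int = 1000
    corrector_steps: int = 1   # Langevin steps per predictor step
    snr: float = 0.16
    seed: int = 0
    denoise_final: bool = True  # Tweedie step x <- x + sigma^2 * s at the end

    def __post_init__(self):
        if self.corrector_steps < 0:
            raise ValueError("corrector_steps must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


def sigma(t, params: VESDEParams):
    """Noise scale sigma(t); strictly increasing, sigma(0/1) = sigma_min/max."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("diffusion time t must lie in [0, 1]")
    out = params.sigma_min * (params.sigma_max / params.sigma_min) ** t
    return float(out) if out.ndim == 0 else out


def perturb(x0: np.ndarray, t, noise: np.ndarray, params: VESDEParams) -> np.ndarray:
    """Forward perturbation x_t = x_0 + sigma(t) * noise (zero drift)."""
    x0 = np.asarray(x0, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if noise.shape != x0.shape:
        raise ValueError(f"noise shape {noise.shape} != x0 shape {x0.shape}")
    s = sigma(t, params)
    s = np.asarray(s)
    if s.ndim == 1:  # per-sample times for a batch
        s = s.reshape((-1,) + (1,) * (x0.ndim - 1))
    return x0 + s * noise


def _wrap_unit(v: np.ndarray) -> np.ndarray:
    return np.mod(np.asarray(v, dtype=float) + 1.0, 2.0) - 1.0


def circular_cut_shifts(x0: np.ndarray, first_angle_col: int = 20) -> np.ndarray:
    """Per-entry re-cut shifts for the circular angle channels.

    Torsion modes that sit at +-180 degrees (omega, trans chi rotamers)
    straddle the wrap of the normalized interval, which a Gaussian diffusion
    on a linear axis cannot represent. For each angle entry the wrap is
    moved to the centre of the emptiest (circularly smoothed) histogram bin
    of the training values; the model then works on z = wrap(x - shift).
    The transform is exactly invertible, so nothing changes outside the
    model internals.
    """
    N, L, F = x0.shape
    shift = np.zeros((L, F))
    for ci in range(first_angle_col, F):
        for li in range(L):
            vals = np.mod(x0[:, li, ci] + 1.0, 2.0)  # [0, 2)
            hist, _ = np.histogram(vals, bins=36, range=(0.0, 2.0))
            smoothed = hist + np.roll(hist, 1) + np.roll(hist, -1)
            cut = (np.argmin(smoothed) + 0.5) * (2.0 / 36) - 1.0
            shift[li, ci] = _wrap_unit(cut + 1.0)  # antipode of the cut
    return shift


class ScoreModel:
    """Trained score estimator s(x, t) = eps_hat(x, sigma(t)) / sigma(t).

    The model operates in its internal ("model space") coordinates: angle
    channels re-cut by the per-entry shifts learned at training time
    (:func:`circular_cut_shifts`). ``to_model_space`` / ``from_model_space``
    convert feature-map arrays; the score callable itself expects and
    returns model-space states (this is what the sampler integrates).
    """

    def __init__(self, net: ScoreNet, params: VESDEParams):
        self.net = net
        self.params = params

    def to_model_space(self, x: np.ndarray) -> np.ndarray:
        z = np.array(x, dtype=float, copy=True)
        z[..., 20:] = _wrap_unit(z[..., 20:] - self.net.x_shift[:, 20:])
        return z

    def from_model_space(self, z: np.ndarray) -> np.ndarray:
        x = np.array(z, dtype=float, copy=True)
        x[..., 20:] = _wrap_unit(x[..., 20:] + self.net.x_shift[:, 20:])
        return x

    def __call__(self, x: np.ndarray, t) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 2
        xb = x[None] if single else x
        tb = np.full(xb.shape[0], float(np.asarray(t).reshape(-1)[0])) if np.ndim(t) == 0 \
            else np.asarray(t, dtype=float)
        s = np.asarray(sigma(tb, self.params))
        eps = self.net.eps(xb, s)
        out = eps / s[:, None, None]
        return out[0] if single else out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.net.save(path)
        side = json.loads(path.with_suffix(".json").read_text())
        side["vesde"] = asdict(self.params)
        path.with_suffix(".json").write_text(json.dumps(side, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ScoreModel":
        path = Path(path)
        side = json.loads(path.with_suffix(".json").read_text())
        vesde = VESDEParams(**side.pop("vesde"))
        net = ScoreNet.load(path)
        return cls(net, vesde)


def _as_batch_array(batch) -> np.ndarray:
    if isinstance(batch, np.ndarray):
        return batch.astype(float)
    return np.stack([m.array() if isinstance(m, HelixFeatureMap) else np.asarray(m) for m in batch])


def dsm_loss(model, batch, t_draws, noise_draws, params: VESDEParams):
    """sigma^2-weighted denoising score-matching loss.

    loss = E_batch[ sigma(t)^2 * || s(x_t, t) + noise / sigma(t) ||^2 ]

    with the norm summed over feature dimensions and the expectation over the
    batch. For a :class:`ScoreModel` the returned value is an autodiff
    :class:`Tensor` (differentiable in the network parameters); for a plain
    score callable it is a float.
    """
    x0 = _as_batch_array(batch)
    if x0.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    if isinstance(model, ScoreModel):
        x0 = model.to_model_space(x0)
    t = np.asarray(t_draws, dtype=float).reshape(-1)
    noise = np.asarray(noise_draws, dtype=float)
    s = np.asarray(sigma(t, params))
    xt = perturb(x0, t, noise, params)
    if isinstance(model, ScoreModel):
        eps_hat = model.net.forward(xt, s)  # Tensor; target: eps_hat = -noise
        resid = eps_hat + Tensor(noise.astype(np.float32))
        return (resid * resid).sum(axis=tuple(range(1, x0.ndim))).mean()
    score_fn = model if callable(model) else None
    if score_fn is None:
        raise TypeError("model must be a ScoreModel or a callable score(x, t)")
    sv = score_fn(xt, t) if _accepts_batch_t(score_fn) else np.stack(
        [score_fn(xt[i], t[i]) for i in range(len(t))]
    )
    sb = s.reshape((-1,) + (1,) * (x0.ndim - 1))
    resid = sb * sv + noise
    return float((resid**2).sum(axis=tuple(range(1, x0.ndim))).mean())


def _accepts_batch_t(fn: Callable) -> bool:
    return getattr(fn, "batched", False)


def train(
    net: ScoreNet,
    train_set: Sequence,
    params: VESDEParams = VESDEParams(),
    epochs: int = 20,
    batch_size: int = 128,
    seed: int = 0,
    lr: float = 1e-3,
    t_floor: float = 1e-5,
    lr_decay: float = 0.1,
    ema_decay: float = 0.999,
) -> tuple[ScoreModel, list[float]]:
    """Train the eps-predictor by denoising score matching.

    Continuous time t ~ U(t_floor, 1) avoids the t=0 singularity; because the
    noise schedule is geometric this is uniform in log(sigma). The learning
    rate decays exponentially to ``lr * lr_decay`` over the run and the
    returned model carries an exponential moving average of the weights
    (decay ``ema_decay``), both standard stabilizers for score models.
    Returns the wrapped :class:`ScoreModel` and the per-epoch mean loss
    trace. Seed-reproducible on CPU; raises on divergent (non-finite) loss.
    """
    x0 = _as_batch_array(train_set)
    if x0.shape[0] == 0:
        raise ValueError("train_set must be nonempty")
    rng = np.random.default_rng(seed)
    # move the wrap of each circular channel away from the data modes,
    # then estimate per-entry mean/scale for the denoiser preconditioning;
    # exact-zero channels (mask padding) keep scale 0 so their denoised
    # value is pinned
    net.x_shift = circular_cut_shifts(x0).astype(np.float32)
    x0 = x0.copy()
    x0[..., 20:] = _wrap_unit(x0[..., 20:] - net.x_shift[:, 20:])
    std = x0.std(axis=0)
    std[std < 1e-6] = 0.0
    net.sigma_data = std.astype(np.float32)
    net.x_mean = x0.mean(axis=0).astype(np.float32)
    opt = Adam(net.params, lr=lr)
    n = x0.shape[0]
    total_steps = max(1, epochs * ((n + batch_size - 1) // batch_size))
    gamma = lr_decay ** (1.0 / total_steps)
    ema = [p.data.copy() for p in net.params]
    trace: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = x0[idx]
            t = rng.uniform(t_floor, 1.0, size=len(idx))
            noise = rng.standard_normal(xb.shape)
            s = np.asarray(sigma(t, params))
            xt = perturb(xb, t, noise, params)
            eps_hat = net.forward(xt, s)
            resid = eps_hat + Tensor(noise.astype(np.float32))
            # per-entry weight (sigma^2 + s_d^2) / s_d^2 makes the effective
            # regression target of the preconditioned network O(1) at every
            # noise level (constant-zero channels carry no loss)
            sd = net.sigma_data[None, :, :]
            sg2 = (s**2)[:, None, None]
            w = np.where(sd > 0, (sg2 + sd**2) / np.maximum(sd, 1e-12) ** 2, 0.0)
            loss = (Tensor(w.astype(np.float32)) * resid * resid).sum(axis=(1, 2)).mean()
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            opt.lr *= gamma
            for e, p in zip(ema, net.params):
                e *= ema_decay
                e += (1.0 - ema_decay) * p.data
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
    for e, p in zip(ema, net.params):
        p.data = e.astype(np.float32)
    return ScoreModel(net, params), trace


def pc_sample(
    score,
    shape: tuple[int, ...],
    sampler: SamplerConfig = SamplerConfig(),
    params: VESDEParams = VESDEParams(),
    n_samples: int = 1,
    hook=None,
) -> np.ndarray:
    """Predictor-corrector reverse-time sampling.

    ``score`` is a :class:`ScoreModel` or any callable ``score(x, t)`` mapping
    a batch (n, *shape) at scalar time t to the score array of the same
    shape. Returns (n_samples, *shape). ``hook(x, t, rng)``, if given, is
    applied to the state after every predictor and corrector step (used for
    inpainting conditioning); it receives and returns the batch array.

    Every sample is driven by its own RNG stream (spawned from the seed) and
    its own Langevin step size, so trajectories are mutually independent:
    sample i is identical whether it is drawn in a batch of 1 or of 1000,
    and best-of-n selections are prefix-consistent in n.
    """
    gens = [np.random.default_rng(c) for c in np.random.SeedSequence(sampler.seed).spawn(n_samples)]

    def draw():
        return np.stack([g.standard_normal(shape) for g in gens])

    N = sampler.n_steps
    x = draw() * params.sigma_max
    tgrid = np.linspace(0.0, 1.0, N + 1)
    sigmas = np.asarray(sigma(tgrid, params))
    flat = (n_samples, -1)

    def score_at(xc, t):
        return np.asarray(score(xc, t), dtype=float)

    def hooked(xc, t):
        return hook(xc, t, gens) if hook is not None else xc

    for i in range(N, 0, -1):
        t_i, t_prev = tgrid[i], tgrid[i - 1]
        # Euler-Maruyama predictor for the reverse SDE
        diff = sigmas[i] ** 2 - sigmas[i - 1] ** 2
        s_val = score_at(x, t_i)
        x = x + diff * s_val + np.sqrt(diff) * draw()
        x = hooked(x, t_prev)
        # Langevin MCMC corrector at the new time
        for _ in range(sampler.corrector_steps):
            s_val = score_at(x, t_prev)
            z = draw()
            s_norm = np.sqrt((s_val.reshape(flat) ** 2).sum(axis=1))
            # ||z|| is taken at its concentration value sqrt(D); reusing the
            # realized norm of the same draw that enters the update would
            # correlate step size and noise and inflate the noise variance
            z_norm = np.sqrt(x[0].size)
            eps = np.where(
                s_norm > 0, 2.0 * (sampler.snr * z_norm / np.maximum(s_norm, 1e-300)) ** 2, 0.0
            )
            # a vanishing score (density ridge) would make the raw step size
            # blow up; sigma^2 caps it at the marginal's own variance scale
            # (the nominal value 2 r^2 sigma^2 is far below the cap)
            eps = np.minimum(eps, sigmas[i - 1] ** 2).reshape((-1,) + (1,) * len(shape))
            x = x + eps * s_val + np.sqrt(2.0 * eps) * z
            x = hooked(x, t_prev)
        if not np.all(np.isfinite(x)):
            raise RuntimeError(f"non-finite sampler state at reverse step {i}")
    if sampler.denoise_final:
        s_val = score_at(x, tgrid[0])
        x = x + sigmas[0] ** 2 * s_val
        x = hooked(x, 0.0)
    return x


def make_replacement_hook(mask: np.ndarray, known: np.ndarray, params: VESDEParams):
    """Replacement-conditioning hook for :func:`pc_sample`.

    At time t the entries where ``mask`` is set are overwritten with the
    forward-perturbed known values, known + sigma(t) * z; at t = 0 they are
    written exactly (hard constraint).
    """
    m = np.asarray(mask, dtype=bool)
    known = np.asarray(known, dtype=float)
    if m.shape != known.shape:
        raise ValueError("mask and known values must share a shape")

    def hook(x, t, gens):
        if t <= 0.0:
            x[:, m] = known[m]
        else:
            z = np.stack([g.standard_normal(m.shape) for g in gens])
            noisy = known[None] + sigma(t, params) * z
            x[:, m] = noisy[:, m]
        return x

    return hook


def sample_feature_maps(
    model: ScoreModel,
    n_samples: int,
    sampler: SamplerConfig = SamplerConfig(),
) -> list[HelixFeatureMap]:
    """Unconditional generation of helix feature maps.

    Integrates the reverse SDE in model space, maps back to feature-map
    coordinates, and attaches the validity mask implied by each sample's
    decoded sequence.
    """
    from .featuremap import standard_valid_mask

    shape = (model.net.L, model.net.F)
    z = pc_sample(model, shape, sampler, model.params, n_samples=n_samples)
    x = model.from_model_space(z)
    out = []
    for xi in x:
        m = HelixFeatureMap.from_array(xi)
        m.valid = standard_valid_mask(m.sequence)
        m.ang[~m.valid] = 0.0
        out.append(m)
    return out
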