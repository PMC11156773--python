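"""GAN inversion: optimize an extended latent code and noise maps to match a target.

The projector initializes the latent from the mean of the top-k of N random
style codes ranked by SSIM against the target (rather than the plain N-sample
mean), then runs Adam over the extended code w+ and all per-layer noise maps.
The loss is a perceptual feature distance plus a heavily weighted
noise-autocorrelation regularizer (weight c = 1e5) that keeps the noise maps
signal-free; after every iteration each noise map is renormalized to zero mean
and unit variance. The learning rate follows a cosine ramp (up over the first
50 iterations, down over the last 250) and decaying Gaussian exploration noise
with std ``0.05 * sigma_w * t^2`` is added to the latent during the first 750
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from . import tensor as T
from .nn import Adam
from .stylegan import GeneratorModel, RandomConvEmbedder, from_unit
from .tensor import Tensor


@dataclass
class ProjectionConfig:
    iterations: int = 3000
    lr_max: float = 0.1
    lr_rampup_iters: int = 50
    lr_rampdown_iters: int = 250
    noise_ramp_iters: int = 750
    noise_factor: float = 0.05
    reg_weight: float = 1e5
    init_samples: int = 10_000
    init_top_k: int = 100
    init_batch: int = 256
    adam_betas: tuple = (0.0, 0.99)
    seed: int = 0

    def __post_init__(self):
        if min(self.iterations, self.lr_rampup_iters, self.lr_rampdown_iters,
               self.noise_ramp_iters, self.init_samples, self.init_top_k) < 1:
            raise ValueError("all iteration/sample counts must be positive")
        if max(self.lr_rampup_iters, self.lr_rampdown_iters) > self.iterations:
            raise ValueError("LR ramps must not exceed iterations")
        if self.init_samples < self.init_top_k:
            raise ValueError("init_samples must be >= init_top_k")


@dataclass
class ProjectionResult:
    wplus: np.ndarray            # (L, d) optimized extended latent
    noise_maps: list[np.ndarray]
    loss_trace: np.ndarray       # (iterations, 3): total, perceptual, regularization
    init_w: np.ndarray
    sigma_w: float

    @property
    def flat(self) -> np.ndarray:
        return self.wplus.reshape(-1)


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Single-scale SSIM, 11x11 Gaussian window (sigma 1.5), averaged over channels."""
    a = np.asarray(a, np.float64)
    b = np.asarray(b, np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    kwargs = dict(gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
                  K1=0.01, K2=0.03, data_range=data_range)
    if a.ndim == 3:
        return float(structural_similarity(a, b, channel_axis=0, **kwargs))
    return float(structural_similarity(a, b, **kwargs))


def init_latent(model: GeneratorModel, target: np.ndarray,
                config: ProjectionConfig) -> tuple[np.ndarray, float]:
    """SSIM-ranked latent initialization.

    Draws ``init_samples`` codes z ~ N(0, I), maps them through G_map,
    synthesizes each with zero noise, and ranks the renderings by SSIM against
    the target. Returns the mean w of the ``init_top_k`` best samples and the
    scalar spread sigma_w (root mean per-component variance) of all sampled w.
    """
    target = np.asarray(target, np.float32)
    if target.shape != (model.cfg.channels, model.resolution, model.resolution):
        raise ValueError("target does not match model resolution/channels")
    rng = np.random.default_rng(config.seed)
    d = model.cfg.latent_dim
    L = model.num_style_layers
    scores = np.empty(config.init_samples)
    ws = np.empty((config.init_samples, d), np.float32)
    for start in range(0, config.init_samples, config.init_batch):
        nb = min(config.init_batch, config.init_samples - start)
        z = rng.standard_normal((nb, d)).astype(np.float32)
        with T.no_grad():
            w = model.mapping(T.tensor(z))
            wp = T.broadcast_to(T.reshape(w, (nb, 1, d)), (nb, L, d))
            raw = model.synthesis(wp, model.make_noise(nb, "zero"))
        imgs = np.clip((raw.data + 1) / 2, 0, 1)
        ws[start:start + nb] = w.data
        for i in range(nb):
            scores[start + i] = ssim(imgs[i], target)
    top = np.argsort(scores)[::-1][:config.init_top_k]
    init_w = ws[top].mean(axis=0)
    sigma_w = float(np.sqrt(ws.var(axis=0).mean()))
    return init_w, sigma_w


def perceptual_distance(a, b, embedder=None) -> float:
    """Sum of squared differences of multi-scale embedder features."""
    a = np.asarray(a, np.float32)
    b = np.asarray(b, np.float32)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    embedder = embedder or RandomConvEmbedder(channels_in=a.shape[0])
    with T.no_grad():
        d = _perceptual_t(T.tensor(a[None]), T.tensor(b[None]), embedder)
    return float(d.item())


def _perceptual_t(a: Tensor, b: Tensor, embedder) -> Tensor:
    fa = embedder.feature_maps(a)
    fb = embedder.feature_maps(b)
    total = None
    for x, y in zip(fa, fb):
        term = T.tsum(T.square(x - y))
        total = term if total is None else total + term
    return total


def noise_reg(stack) -> float:
    """Autocorrelation penalty of a stack of noise maps (Eq.-style pyramid sum).

    Each map is average-pooled (with x2 amplitude compensation, so unit
    variance is preserved) down to 8x8; at every pyramid level the penalty is
    ``(sum(p * roll_x(p)) / r^2)^2 * r^2``-normalized, i.e.
    ``(1/r^2) (sum p p_x)^2 + (1/r^2) (sum p p_y)^2`` with circular shifts.
    """
    total = _noise_reg_t([m if isinstance(m, Tensor) else T.tensor(np.asarray(m, np.float32))
                          for m in _as_list(stack)])
    return float(total.item())


def _as_list(stack):
    return list(stack) if isinstance(stack, (list, tuple)) else [stack]


def _noise_reg_t(maps: list[Tensor]) -> Tensor:
    total = None
    for m in maps:
        if m.shape[-1] < 8 or m.shape[-2] < 8:
            raise ValueError("noise maps must be at least 8x8")
        p = m if m.ndim == 4 else T.reshape(m, (1, 1) + tuple(m.shape[-2:]))
        while True:
            r = p.shape[-1]
            inv_r2 = np.float32(1.0 / (r * r))
            tx = T.square(T.tsum(p * T.roll(p, 1, p.ndim - 1))) * inv_r2
            ty = T.square(T.tsum(p * T.roll(p, 1, p.ndim - 2))) * inv_r2
            term = tx + ty
            total = term if total is None else total + term
            if r <= 8:
                break
            p = T.sumpool2x(p) * np.float32(0.5)  # avg pool with x2 amplitude compensation
        if total is None:  # pragma: no cover - unreachable, loop always adds
            raise AssertionError
    return total if total is not None else T.tensor(np.zeros((), np.float32))


def lr_schedule(it: int, config: ProjectionConfig) -> float:
    """Cosine ramp 0 -> lr_max over the first rampup iterations, plateau, then
    cosine ramp to exactly 0 at the final iteration."""
    n = config.iterations
    if not 0 <= it < n:
        raise ValueError(f"iteration {it} out of range [0, {n})")
    up, down = config.lr_rampup_iters, config.lr_rampdown_iters
    t_up = min(1.0, it / up)
    t_down = min(1.0, (n - 1 - it) / max(down - 1, 1))
    t = min(t_up, t_down)
    return config.lr_max * 0.5 * (1 - np.cos(np.pi * t))


def latent_noise_std(it: int, sigma_w: float, config: ProjectionConfig) -> float:
    """Exploration-noise std: ``noise_factor * sigma_w * t^2`` with t ramping 1 -> 0."""
    if it < 0:
        raise ValueError("iteration must be >= 0")
    t = max(0.0, 1.0 - it / config.noise_ramp_iters)
    return config.noise_factor * sigma_w * t * t


def project(model: GeneratorModel, target: np.ndarray,
            config: ProjectionConfig | None = None, embedder=None,
            init: tuple[np.ndarray, float] | None = None) -> ProjectionResult:
    """Invert ``target`` (C, H, W in [0, 1]) into W+ plus noise maps."""
    config = config or ProjectionConfig()
    target = np.asarray(target, np.float32)
    if target.shape != (model.cfg.channels, model.resolution, model.resolution):
        raise ValueError("target does not match model resolution/channels")
    embedder = embedder or RandomConvEmbedder(channels_in=model.cfg.channels)
    init_w, sigma_w = init if init is not None else init_latent(model, target, config)

    rng = np.random.default_rng(config.seed + 1)
    L, d = model.num_style_layers, model.cfg.latent_dim
    wplus = T.tensor(np.repeat(init_w[None, None], L, axis=1).astype(np.float32),
                     requires_grad=True)
    noise_maps = [T.tensor(rng.standard_normal((1, 1, h, w)).astype(np.float32),
                           requires_grad=True)
                  for (h, w) in model.synthesis.noise_shapes]
    reg_maps = [m for m in noise_maps if m.shape[-1] >= 8]
    params = [wplus] + noise_maps
    opt = Adam(params, lr=config.lr_max, betas=config.adam_betas)
    target_t = T.tensor(from_unit(target)[None])
    gen_params = model.parameters()
    frozen = [p.requires_grad for p in gen_params]
    for p in gen_params:
        p.requires_grad = False

    trace = np.zeros((config.iterations, 3))
    try:
        for it in range(config.iterations):
            std = latent_noise_std(it, sigma_w, config)
            w_in = wplus
            if std > 0:
                w_in = wplus + T.tensor(
                    rng.normal(0.0, std, wplus.shape).astype(np.float32))
            raw = model.synthesis(w_in, noise_maps)
            percep = _perceptual_t(raw, target_t, embedder)
            reg = _noise_reg_t(reg_maps)
            loss = percep + reg * np.float32(config.reg_weight)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at iteration {it}; trace so far: {trace[:it]}")
            grads = T.grad(loss, params)
            opt.lr = lr_schedule(it, config)
            opt.step([g.data for g in grads])
            for m in noise_maps:
                mu = m.data.mean()
                sd = m.data.std()
                m.data = (m.data - mu) / max(sd, 1e-8)
            trace[it] = (loss.item(), percep.item(), reg.item() * config.reg_weight)
    finally:
        for p, flag in zip(gen_params, frozen):
            p.requires_grad = flag

    return ProjectionResult(
        wplus=wplus.data[0].copy(),
        noise_maps=[m.data[0, 0].copy() for m in noise_maps],
        loss_trace=trace,
        init_w=init_w,
        sigma_w=sigma_w,
    )
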