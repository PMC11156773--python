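"""Scaled-down style-based GAN: generator, discriminator, training, quality metric.

The generator has a 4-layer fully connected mapping network Z -> W and a
style-modulated synthesis network W -> X growing from 4x4 to the target
resolution, with per-layer noise injection. The discriminator is a residual
downsampling network with a minibatch standard-deviation layer. Training uses
the non-saturating logistic loss with lazy R1 regularization, Adam with
betas (0, 0.99), and adaptive discriminator augmentation restricted to
horizontal mirroring. Generated and real sets are compared with the Fréchet
distance between Gaussian fits of a pluggable feature embedding.

Defaults are desk-scale (64-dimensional latents, 32-64 px); the architecture
itself is resolution- and width-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.linalg

from . import nn
from . import tensor as T
from .nn import Adam, Conv, Dense, ModConv, Module
from .tensor import Tensor

DEFAULT_WIDTHS = {4: 64, 8: 48, 16: 32, 32: 24, 64: 16, 128: 12}


def num_style_layers(resolution: int) -> int:
    return 2 * int(np.log2(resolution)) - 2


@dataclass
class GeneratorConfig:
    resolution: int = 32
    latent_dim: int = 64
    channels: int = 3
    widths: dict = field(default_factory=lambda: dict(DEFAULT_WIDTHS))
    mapping_layers: int = 4
    mapping_lr_mul: float = 0.01
    seed: int = 0

    def __post_init__(self):
        r = self.resolution
        if r < 8 or (r & (r - 1)) != 0:
            raise ValueError(f"resolution must be a power of two >= 8, got {r}")


@dataclass
class TrainConfig:
    learning_rate: float = 0.0025
    adam_betas: tuple = (0.0, 0.99)
    adam_eps: float = 1e-8
    r1_gamma: float = 1.0
    r1_interval: int = 16
    ada_target: float = 0.6
    ada_step: float = 0.01
    mirror_augment: bool = True
    kimg_budget: float = 4.0
    batch_size: int = 16
    metric_interval: int = 100
    metric_samples: int = 128
    seed: int = 0


class MappingNetwork(Module):
    def __init__(self, rng, latent_dim: int, n_layers: int, lr_mul: float):
        self.layers = [Dense(rng, latent_dim, latent_dim, lr_mul=lr_mul)
                       for _ in range(n_layers)]

    def __call__(self, z: Tensor) -> Tensor:
        # pixel-norm the input latent
        x = z * T.power(T.tmean(T.square(z), axis=-1, keepdims=True) + np.float32(1e-8), -0.5)
        for layer in self.layers:
            x = nn.lrelu(layer(x))
        return x


class SynthesisNetwork(Module):
    """4x4 learned constant -> modulated conv stack -> linear toRGB."""

    def __init__(self, rng, cfg: GeneratorConfig):
        self.cfg = cfg
        d = cfg.latent_dim
        w4 = cfg.widths[4]
        self.const = T.tensor(rng.standard_normal((1, w4, 4, 4)).astype(np.float32),
                              requires_grad=True)
        self.conv0 = ModConv(rng, w4, w4, d)
        self.noise_gains = [T.tensor(np.zeros((), np.float32), requires_grad=True)]
        self.noise_shapes = [(4, 4)]
        self.blocks: list[list[ModConv]] = []
        res, c_prev = 4, w4
        while res < cfg.resolution:
            res *= 2
            c = cfg.widths[res]
            conv_a = ModConv(rng, c_prev, c, d)
            conv_b = ModConv(rng, c, c, d)
            self.blocks.append([conv_a, conv_b])
            for _ in range(2):
                self.noise_gains.append(T.tensor(np.zeros((), np.float32), requires_grad=True))
                self.noise_shapes.append((res, res))
            c_prev = c
        self.to_rgb = ModConv(rng, c_prev, cfg.channels, d, k=1, demodulate=False)

    @property
    def num_layers(self) -> int:
        return num_style_layers(self.cfg.resolution)

    def parameters(self) -> list[Tensor]:
        params = [self.const] + list(self.noise_gains)
        params += self.conv0.parameters()
        for a, b in self.blocks:
            params += a.parameters() + b.parameters()
        params += self.to_rgb.parameters()
        return params

    def __call__(self, wplus: Tensor, noise: list[Tensor]) -> Tensor:
        B = wplus.shape[0]
        x = T.broadcast_to(self.const, (B,) + self.const.shape[1:])

        def style(i):
            return T.reshape(T.narrow(wplus, 1, i, 1), (B, self.cfg.latent_dim))

        def inject(x, idx):
            return x + noise[idx] * self.noise_gains[idx]

        x = nn.lrelu(inject(self.conv0(x, style(0)), 0))
        si, ni = 1, 1
        for conv_a, conv_b in self.blocks:
            x = nn.upsample_bilinear(x)
            x = nn.lrelu(inject(conv_a(x, style(si)), ni))
            x = nn.lrelu(inject(conv_b(x, style(si + 1)), ni + 1))
            si += 2
            ni += 2
        return self.to_rgb(x, style(self.num_layers - 1))


class GeneratorModel(Module):
    """Mapping network G_map: Z -> W plus synthesis network G_syn: W -> X."""

    def __init__(self, cfg: GeneratorConfig | None = None):
        self.cfg = cfg or GeneratorConfig()
        rng = np.random.default_rng(self.cfg.seed)
        self.mapping = MappingNetwork(rng, self.cfg.latent_dim, self.cfg.mapping_layers,
                                      self.cfg.mapping_lr_mul)
        self.synthesis = SynthesisNetwork(rng, self.cfg)

    @property
    def num_style_layers(self) -> int:
        return self.synthesis.num_layers

    @property
    def resolution(self) -> int:
        return self.cfg.resolution

    def make_noise(self, batch: int = 1, mode: str = "zero",
                   rng: np.random.Generator | None = None) -> list[Tensor]:
        maps = []
        for (h, w) in self.synthesis.noise_shapes:
            if mode == "zero":
                arr = np.zeros((batch, 1, h, w), np.float32)
            elif mode == "random":
                if rng is None:
                    rng = np.random.default_rng()
                arr = rng.standard_normal((batch, 1, h, w)).astype(np.float32)
            else:
                raise ValueError(f"unknown noise mode: {mode!r}")
            maps.append(T.tensor(arr))
        return maps


class Discriminator(Module):
    def __init__(self, cfg: GeneratorConfig):
        rng = np.random.default_rng(cfg.seed + 1)
        self.cfg = cfg
        widths = cfg.widths
        self.from_rgb = Conv(rng, cfg.channels, widths[cfg.resolution], k=1)
        self.blocks = []
        res = cfg.resolution
        while res > 4:
            c_in, c_out = widths[res], widths[res // 2]
            self.blocks.append([Conv(rng, c_in, c_in, k=3),
                                Conv(rng, c_in, c_out, k=3),
                                Conv(rng, c_in, c_out, k=1)])  # residual skip
            res //= 2
        w4 = widths[4]
        self.conv_final = Conv(rng, w4 + 1, w4, k=3)
        self.dense = Dense(rng, w4 * 16, w4)
        self.out = Dense(rng, w4, 1)

    def parameters(self) -> list[Tensor]:
        params = self.from_rgb.parameters()
        for conv1, conv2, skip in self.blocks:
            params += conv1.parameters() + conv2.parameters() + skip.parameters()
        params += self.conv_final.parameters() + self.dense.parameters() + self.out.parameters()
        return params

    def __call__(self, x: Tensor) -> Tensor:
        h = nn.lrelu(self.from_rgb(x))
        for conv1, conv2, skip in self.blocks:
            y = nn.lrelu(conv1(h))
            y = nn.lrelu(conv2(nn.downsample_avg(y)))
            h = (y + nn.downsample_avg(skip(h))) * np.float32(1 / np.sqrt(2))
        h = nn.minibatch_std(h)
        h = nn.lrelu(self.conv_final(h))
        B = h.shape[0]
        h = T.reshape(h, (B, h.shape[1] * 16))
        h = nn.lrelu(self.dense(h))
        return self.out(h)


# -- public functional API -----------------------------------------------------

def map_latent(model: GeneratorModel, z: np.ndarray) -> np.ndarray:
    """Map latent(s) z through G_map; accepts (d,) or (B, d)."""
    z = np.asarray(z, dtype=np.float32)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    single = z.ndim == 1
    if z.shape[-1] != model.cfg.latent_dim:
        raise ValueError(f"latent dim mismatch: expected {model.cfg.latent_dim}")
    with T.no_grad():
        w = model.mapping(T.tensor(np.atleast_2d(z)))
    return w.data[0] if single else w.data


def synthesize(model: GeneratorModel, wplus: np.ndarray, noise="zero") -> np.ndarray:
    """Generate an image from an extended latent; returns (C, H, W) in [0, 1].

    ``wplus`` may be (d,) — broadcast to all style layers — or (L, d). ``noise``
    is "zero", "random", or an explicit list of per-layer maps.
    """
    wplus = np.asarray(wplus, dtype=np.float32)
    L = model.num_style_layers
    if wplus.ndim == 1:
        wplus = np.repeat(wplus[None], L, axis=0)
    if wplus.shape != (L, model.cfg.latent_dim):
        raise ValueError(f"wplus must be ({L}, {model.cfg.latent_dim}), got {wplus.shape}")
    if isinstance(noise, str):
        noise_t = model.make_noise(1, mode=noise)
    else:
        noise_t = [m if isinstance(m, Tensor) else T.tensor(np.asarray(m, np.float32))
                   for m in noise]
    with T.no_grad():
        raw = model.synthesis(T.tensor(wplus[None]), noise_t)
    return to_unit(raw.data[0])


def to_unit(raw: np.ndarray) -> np.ndarray:
    """Map raw generator output (approx. [-1, 1]) to unit intensity range."""
    return np.clip((raw + 1.0) / 2.0, 0.0, 1.0)


def from_unit(img: np.ndarray) -> np.ndarray:
    return img.astype(np.float32) * 2.0 - 1.0


def r1_penalty(discriminator, real_images: np.ndarray, gamma: float = 1.0):
    """R1 regularizer (gamma/2) E[ ||grad_x D(x)||^2 ] with a differentiable graph.

    Returns a scalar Tensor so it can be added to the discriminator loss.
    """
    x = T.tensor(np.asarray(real_images, np.float32), requires_grad=True)
    out = discriminator(x)
    (gx,) = T.grad(out.sum(), [x], create_graph=True)
    per_sample = T.tsum(T.square(gx), axis=tuple(range(1, gx.ndim)))
    return T.tmean(per_sample) * np.float32(gamma / 2.0)


def ada_controller_step(p: float, rt: float, config: TrainConfig) -> float:
    """Adjust the mirroring probability from the discriminator-overfitting statistic."""
    if rt > config.ada_target:
        p = p + config.ada_step
    else:
        p = p - config.ada_step
    return float(np.clip(p, 0.0, 1.0))


# -- Fréchet metric ------------------------------------------------------------

class RandomConvEmbedder(Module):
    """Fixed-seed random convolutional feature extractor.

    Serves as the pluggable embedder for both the Fréchet quality metric and
    the perceptual distance. Any object exposing ``feature_maps`` (list of
    tensors) and ``embed`` (pooled feature matrix) — e.g. a pretrained
    backbone wrapper — can stand in for it.
    """

    def __init__(self, channels_in: int = 3, widths: tuple = (12, 16, 16), seed: int = 1234):
        rng = np.random.default_rng(seed)
        self.convs = []
        c = channels_in
        for w in widths:
            conv = Conv(rng, c, w, k=3)
            for p in conv.parameters():
                p.requires_grad = False
            self.convs.append(conv)
            c = w

    def feature_maps(self, x: Tensor) -> list[Tensor]:
        feats = []
        h = x
        for conv in self.convs:
            h = T.leaky_relu(conv(h), 0.2)
            feats.append(h)
            if h.shape[-1] >= 8:
                h = T.sumpool2x(h) * np.float32(0.25)
            else:
                break
        return feats

    def embed(self, images: np.ndarray) -> np.ndarray:
        """(N, C, H, W) -> (N, F) spatially pooled features."""
        out = []
        with T.no_grad():
            for i in range(0, len(images), 64):
                batch = T.tensor(np.asarray(images[i:i + 64], np.float32))
                feats = self.feature_maps(batch)
                pooled = [f.data.mean(axis=(2, 3)) for f in feats]
                out.append(np.concatenate(pooled, axis=1))
        return np.concatenate(out, axis=0)


def gaussian_stats(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = features.mean(axis=0)
    cov = np.cov(features, rowvar=False)
    return mu, np.atleast_2d(cov)


def frechet_distance(mean1, cov1, mean2, cov2, psd_tol: float = 1e-6) -> float:
    """d^2 = ||mu1-mu2||^2 + tr(S1 + S2 - 2 (S1 S2)^(1/2)) between two Gaussians."""
    mu1, mu2 = np.atleast_1d(mean1), np.atleast_1d(mean2)
    s1, s2 = np.atleast_2d(cov1), np.atleast_2d(cov2)
    for s in (s1, s2):
        if not np.allclose(s, s.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        w = np.linalg.eigvalsh(s)
        if w.min() < -psd_tol * max(1.0, abs(w.max())):
            raise ValueError("covariance must be positive semidefinite")
    covmean = scipy.linalg.sqrtm(s1 @ s2)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    d2 = float(np.sum((mu1 - mu2) ** 2) + np.trace(s1 + s2 - 2.0 * covmean))
    return max(d2, 0.0)


def frechet_between_sets(real: np.ndarray, fake: np.ndarray, embedder=None) -> float:
    embedder = embedder or RandomConvEmbedder(channels_in=real.shape[1])
    mu1, s1 = gaussian_stats(embedder.embed(real))
    mu2, s2 = gaussian_stats(embedder.embed(fake))
    return frechet_distance(mu1, s1, mu2, s2)


# -- training ------------------------------------------------------------------

@dataclass
class TrainResult:
    model: GeneratorModel
    discriminator: Discriminator
    history: dict


def _mirror_some(images: Tensor, n_flip: int) -> Tensor:
    if n_flip == 0:
        return images
    flipped = T.flip(T.narrow(images, 0, 0, n_flip), 3)
    if n_flip == images.shape[0]:
        return flipped
    rest = T.narrow(images, 0, n_flip, images.shape[0] - n_flip)
    return T.concat([flipped, rest], axis=0)


def train(dataset: np.ndarray, config: TrainConfig | None = None,
          gen_config: GeneratorConfig | None = None,
          embedder=None, log_fn=None) -> TrainResult:
    """Adversarial training on a stack of images (N, C, H, W) in [0, 1].

    Alternates discriminator and generator Adam steps with non-saturating
    logistic losses, applies R1 lazily every ``r1_interval`` steps, and mirrors
    minibatches horizontally with a probability driven by the ADA controller.
    """
    config = config or TrainConfig()
    dataset = np.asarray(dataset, np.float32)
    if dataset.ndim != 4 or len(dataset) == 0:
        raise ValueError("dataset must be a non-empty (N, C, H, W) stack")
    res = dataset.shape[-1]
    if dataset.shape[-2] != res or (res & (res - 1)) != 0:
        raise ValueError("images must be square with power-of-two resolution")
    gen_config = gen_config or GeneratorConfig(resolution=res, channels=dataset.shape[1],
                                               seed=config.seed)
    if gen_config.resolution != res:
        raise ValueError("generator resolution does not match dataset")

    rng = np.random.default_rng(config.seed)
    G = GeneratorModel(gen_config)
    D = Discriminator(gen_config)
    g_params, d_params = G.parameters(), D.parameters()
    opt_g = Adam(g_params, lr=config.learning_rate, betas=config.adam_betas,
                 eps=config.adam_eps)
    opt_d = Adam(d_params, lr=config.learning_rate, betas=config.adam_betas,
                 eps=config.adam_eps)
    data_raw = from_unit(dataset)
    L = G.num_style_layers
    d_lat = gen_config.latent_dim
    B = min(config.batch_size, len(dataset))
    n_steps = max(1, int(config.kimg_budget * 1000 / B))

    history = {"step": [], "loss_g": [], "loss_d": [], "ada_p": [],
               "frechet": [], "frechet_step": []}
    if embedder is None:
        embedder = RandomConvEmbedder(channels_in=dataset.shape[1])
    ada_p = 0.0

    def gen_batch(create_graph: bool):
        z = rng.standard_normal((B, d_lat)).astype(np.float32)
        w = G.mapping(T.tensor(z))
        wplus = T.broadcast_to(T.reshape(w, (B, 1, d_lat)), (B, L, d_lat))
        noise = G.make_noise(B, mode="random", rng=rng)
        return G.synthesis(wplus, noise)

    for step in range(n_steps):
        n_flip = int(rng.binomial(B, ada_p)) if config.mirror_augment else 0

        # --- discriminator step
        real = data_raw[rng.integers(0, len(dataset), B)]
        if n_flip:
            real = real.copy()
            real[:n_flip] = real[:n_flip, :, :, ::-1]
        with T.no_grad():
            fake = gen_batch(False)
        fake_t = _mirror_some(T.tensor(fake.data), n_flip)
        real_scores = D(T.tensor(real))
        fake_scores = D(fake_t)
        loss_d = T.tmean(T.softplus(fake_scores)) + T.tmean(T.softplus(T.neg(real_scores)))
        if config.r1_gamma > 0 and step % config.r1_interval == 0:
            loss_d = loss_d + r1_penalty(D, real, config.r1_gamma) \
                * np.float32(config.r1_interval)
        grads = T.grad(loss_d, d_params)
        opt_d.step([g.data for g in grads])

        rt = float(np.sign(real_scores.data).mean())
        if config.mirror_augment:
            ada_p = ada_controller_step(ada_p, rt, config)

        # --- generator step
        fake = gen_batch(True)
        fake_aug = _mirror_some(fake, n_flip)
        loss_g = T.tmean(T.softplus(T.neg(D(fake_aug))))
        grads = T.grad(loss_g, g_params)
        opt_g.step([g.data for g in grads])

        if not (np.isfinite(loss_d.item()) and np.isfinite(loss_g.item())):
            raise FloatingPointError(f"non-finite loss at step {step}")

        history["step"].append(step)
        history["loss_g"].append(float(loss_g.item()))
        history["loss_d"].append(float(loss_d.item()))
        history["ada_p"].append(ada_p)
        if step % config.metric_interval == 0 or step == n_steps - 1:
            n_m = min(config.metric_samples, len(dataset))
            idx = rng.integers(0, len(dataset), n_m)
            with T.no_grad():
                z = rng.standard_normal((n_m, d_lat)).astype(np.float32)
                w = G.mapping(T.tensor(z))
                wp = T.broadcast_to(T.reshape(w, (n_m, 1, d_lat)), (n_m, L, d_lat))
                fakes = to_unit(G.synthesis(wp, G.make_noise(n_m, "random", rng)).data)
            fd = frechet_between_sets(dataset[idx], fakes, embedder)
            history["frechet"].append(fd)
            history["frechet_step"].append(step)
            if log_fn is not None:
                log_fn({"step": step, "loss_g": history["loss_g"][-1],
                        "loss_d": history["loss_d"][-1], "ada_p": ada_p, "frechet": fd})
    return TrainResult(model=G, discriminator=D, history=history)


# -- checkpointing -------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path, model: GeneratorModel, discriminator: Discriminator | None = None,
                    extra: dict | None = None) -> None:
    cfg = asdict(model.cfg)
    cfg["widths"] = {str(k): v for k, v in cfg["widths"].items()}
    payload = {
        "version": np.array(CHECKPOINT_VERSION),
        "config_json": np.array(json.dumps(cfg)),
        "extra_json": np.array(json.dumps(extra or {})),
    }
    for i, arr in enumerate(model.state_arrays()):
        payload[f"g_{i}"] = arr
    if discriminator is not None:
        for i, arr in enumerate(discriminator.state_arrays()):
            payload[f"d_{i}"] = arr
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[GeneratorModel, Discriminator | None, dict]:
    with np.load(path, allow_pickle=False) as data:
        if "version" not in data or int(data["version"]) != CHECKPOINT_VERSION:
            raise ValueError("unsupported or missing checkpoint version")
        cfg_d = json.loads(str(data["config_json"]))
        cfg_d["widths"] = {int(k): v for k, v in cfg_d["widths"].items()}
        cfg = GeneratorConfig(**cfg_d)
        model = GeneratorModel(cfg)
        g_arrays = [data[f"g_{i}"] for i in range(len(model.parameters()))]
        model.load_arrays(g_arrays)
        disc = None
        if "d_0" in data:
            disc = Discriminator(cfg)
            d_arrays = [data[f"d_{i}"] for i in range(len(disc.parameters()))]
            disc.load_arrays(d_arrays)
        extra = json.loads(str(data["extra_json"]))
    return model, disc, extra
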