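"""Neural-network building blocks on top of the autodiff engine.

Conventions follow the style-based GAN family: equalized learning rate
(weights stored as N(0,1), scaled by the He constant at use time), leaky ReLU
with slope 0.2, weight (de)modulation instead of instance normalization, and
binomial-blurred 2x resampling.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

LRELU_SLOPE = 0.2
_BLUR = np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 16.0


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype)


def _param(rng: np.random.Generator, shape, std: float = 1.0) -> Tensor:
    return T.tensor(rng.standard_normal(shape).astype(np.float32) * std, requires_grad=True)


def _zeros(shape) -> Tensor:
    return T.tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int, lr_mul: float = 1.0, bias_init: float = 0.0):
        # weights stored at std 1/lr_mul and scaled by lr_mul at use time, so the
        # effective init is He-normal while optimizer steps are damped by lr_mul
        self.weight = _param(rng, (n_out, n_in), std=1.0 / lr_mul)
        self.bias = T.tensor(np.full(n_out, bias_init, dtype=np.float32), requires_grad=True)
        self.scale = lr_mul / np.sqrt(n_in)
        self.lr_mul = lr_mul

    def __call__(self, x: Tensor) -> Tensor:
        w = T.transpose(self.weight, (1, 0)) * np.float32(self.scale)
        return x @ w + self.bias * np.float32(self.lr_mul)


class Conv(Module):
    """Plain shared-weight convolution, stride 1, same padding."""

    def __init__(self, rng, c_in: int, c_out: int, k: int = 3):
        self.weight = _param(rng, (c_out, c_in, k, k))
        self.bias = _zeros(c_out)
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.scale = 1.0 / np.sqrt(c_in * k * k)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        cols = T.im2col(x, self.k)
        wm = T.reshape(self.weight, (self.c_out, self.c_in * self.k * self.k))
        y = (wm * np.float32(self.scale)) @ cols
        y = T.reshape(y, (B, self.c_out, H, W))
        return y + T.reshape(self.bias, (1, self.c_out, 1, 1))


class ModConv(Module):
    """Style-modulated convolution with optional weight demodulation.

    Equivalent to per-sample weight modulation: input channels are scaled by
    the affine style, convolved with shared weights, and the output channels
    rescaled by the demodulation factor computed from the modulated weights.
    """

    def __init__(self, rng, c_in: int, c_out: int, style_dim: int, k: int = 3,
                 demodulate: bool = True):
        self.weight = _param(rng, (c_out, c_in, k, k))
        self.bias = _zeros(c_out)
        self.affine = Dense(rng, style_dim, c_in, bias_init=1.0)
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.demodulate = demodulate
        self.scale = 1.0 / np.sqrt(c_in * k * k)

    def __call__(self, x: Tensor, w: Tensor) -> Tensor:
        B, C, H, W = x.shape
        s = self.affine(w)  # (B, c_in)
        xs = x * T.reshape(s, (B, self.c_in, 1, 1))
        cols = T.im2col(xs, self.k)
        wm = T.reshape(self.weight, (self.c_out, self.c_in * self.k * self.k))
        y = (wm * np.float32(self.scale)) @ cols
        y = T.reshape(y, (B, self.c_out, H, W))
        if self.demodulate:
            w2 = T.tsum(T.square(T.reshape(self.weight, (self.c_out, self.c_in, self.k * self.k))
                                 * np.float32(self.scale)), axis=2)  # (c_out, c_in)
            sig2 = T.square(s) @ T.transpose(w2, (1, 0))  # (B, c_out)
            d = T.power(sig2 + np.float32(1e-8), -0.5)
            y = y * T.reshape(d, (B, self.c_out, 1, 1))
        return y + T.reshape(self.bias, (1, self.c_out, 1, 1))


def blur3(x: Tensor) -> Tensor:
    """Binomial 3x3 blur with circular boundary (background is ~0 at edges)."""
    return T.blur3(x)


def upsample_bilinear(x: Tensor) -> Tensor:
    return blur3(T.upsample2x(x))


def downsample_avg(x: Tensor) -> Tensor:
    return T.sumpool2x(blur3(x)) * np.float32(0.25)


def lrelu(x: Tensor) -> Tensor:
    # sqrt(2) gain keeps activation variance roughly constant
    return T.leaky_relu(x, LRELU_SLOPE) * np.float32(np.sqrt(2.0))


def minibatch_std(x: Tensor) -> Tensor:
    """Append one channel holding the mean cross-batch standard deviation."""
    B, C, H, W = x.shape
    mu = T.tmean(x, axis=0, keepdims=True)
    var = T.tmean(T.square(x - mu), axis=0, keepdims=True)
    std = T.power(T.tmean(var) + np.float32(1e-8), 0.5)
    feat = T.broadcast_to(T.reshape(std, (1, 1, 1, 1)), (B, 1, H, W))
    return T.concat([x, feat], axis=1)


class Adam:
    """Adam over a list of parameter tensors; ``lr`` may change between steps."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.0, 0.99), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
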