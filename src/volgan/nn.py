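"""Layer and optimizer kit on top of :mod:`volgan.autodiff`.

Convolution and dense layers use equalized learning rate by default: weights
are stored unit-normal and rescaled at run time by ``gain / sqrt(fan_in)``
(the ProGAN trick that keeps effective per-layer learning rates comparable).
It can be switched off per layer.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Parameter", "Module", "Dense", "Conv3", "Conv1x1", "Adam",
           "pixel_norm", "conv1x1_apply"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal parameter container with named flattening."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self) -> list:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(np.float32).copy()

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 gain: float = np.sqrt(2.0), eq_lr: bool = True,
                 bias_init: float = 0.0):
        self.eq_lr = eq_lr
        if eq_lr:
            self.scale = float(gain / np.sqrt(n_in))
            w = rng.standard_normal((n_in, n_out))
        else:
            self.scale = 1.0
            w = rng.standard_normal((n_in, n_out)) * gain / np.sqrt(n_in)
        self.w = Parameter(w)
        self.b = Parameter(np.full(n_out, bias_init))

    def effective_weight(self) -> np.ndarray:
        """The (n_out, n_in) linear map actually applied, as plain numpy."""
        return (self.w.data * self.scale).T

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.w) * self.scale + self.b


class Conv3(Module):
    """3x3x3 convolution, optionally strided, 'same' padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1, gain: float = np.sqrt(2.0), eq_lr: bool = True):
        fan_in = c_in * 27
        if eq_lr:
            self.scale = float(gain / np.sqrt(fan_in))
            w = rng.standard_normal((c_out, c_in, 3, 3, 3))
        else:
            self.scale = 1.0
            w = rng.standard_normal((c_out, c_in, 3, 3, 3)) * gain / np.sqrt(fan_in)
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(c_out))
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.conv3d(x, self.w, stride=self.stride, pad=1) * self.scale
        return y + ad.reshape(self.b, (1, -1, 1, 1, 1))


def conv1x1_apply(x: Tensor, w: Tensor, b: Tensor, scale: float) -> Tensor:
    """Pointwise channel mix as a matmul composition (B,C,D,H,W) -> (B,O,D,H,W)."""
    B, C = x.shape[0], x.shape[1]
    spatial = x.shape[2:]
    n = int(np.prod(spatial))
    flat = ad.reshape(x, (B, C, n))
    flat = ad.transpose(flat, (0, 2, 1))
    y = ad.matmul(flat, w) * scale + b
    y = ad.transpose(y, (0, 2, 1))
    return ad.reshape(y, (B, w.shape[1]) + tuple(spatial))


class Conv1x1(Module):
    """1x1x1 convolution: the to/from-image converters of the growing ladder."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 gain: float = 1.0, eq_lr: bool = True):
        if eq_lr:
            self.scale = float(gain / np.sqrt(c_in))
            w = rng.standard_normal((c_in, c_out))
        else:
            self.scale = 1.0
            w = rng.standard_normal((c_in, c_out)) * gain / np.sqrt(c_in)
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1x1_apply(x, self.w, self.b, self.scale)


def pixel_norm(x: Tensor, eps: float = 1e-8) -> Tensor:
    """Scale each voxel's channel vector to unit RMS (channel axis = 1)."""
    ms = ad.tmean(x * x, axis=1, keepdims=True)
    return x / ad.sqrt(ms + eps)


class Adam:
    """Standard Adam on a fixed parameter list."""

    def __init__(self, params: list, lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: list):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
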