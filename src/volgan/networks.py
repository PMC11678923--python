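"""Volumetric generator, critic and encoder architectures.

Two generator families share one progressive-growing skeleton:

* **progressive generator** — a dense layer maps the 512-dim latent ``z`` to an
  ``8c``-channel tensor on a coarse grid of one thirty-second of the target
  extent per axis; five stages of (nearest-neighbour upsampling + two 3x3x3
  convolutions) then double the resolution each time, with channel widths
  ``(8c, 8c, 4c, 2c, c)``.  A 1x1x1 "to-image" convolution exists at every
  stage so partially grown networks can emit images and fade smoothly into the
  next stage.

* **style-based generator** — the latent is first pushed through a mapping
  network ``phi`` into an intermediate space ``W``; 15 learned affine heads
  (three per stage) turn ``w`` into per-layer style vectors that modulate the
  convolution weights (weight demodulation), and a per-layer scaled noise map
  is added after each convolution.  Synthesis starts from a learned constant
  tensor.

The critic is a patch critic: five strided 3x3x3 convolutions with increasing
channel count and a final 1x1x1 score convolution whose spatial map is reduced
by the mean.  The encoder used for GAN inversion reverses the generator, with
pixel-feature normalization removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Adam, Conv1x1, Conv3, Dense, Module, Parameter, conv1x1_apply, pixel_norm

__all__ = [
    "ModelConfig", "StageState", "N_STAGES", "LATENT_DIM", "N_STYLES",
    "sample_latent", "channel_schedule", "stage_resolution",
    "ProGANGenerator", "MappingNetwork", "StyleSynthesis", "StyleGenerator",
    "Critic", "Encoder", "LatentDiscriminator",
    "demodulated_conv", "inject_noise", "avgpool2",
]

N_STAGES = 5
LATENT_DIM = 512
STYLES_PER_STAGE = 3
N_STYLES = N_STAGES * STYLES_PER_STAGE  # 15


@dataclass
class ModelConfig:
    """Architecture hyperparameters shared by generator, critic and encoder.

    ``grid`` is the full-resolution spatial extent ``(d1, d2, d3)``; every
    entry must be divisible by 32 so the five doubling stages land exactly on
    it.  ``c_gen`` / ``c_critic`` are the base channel widths (``cg`` and
    ``cc``).
    """

    grid: tuple = (32, 288, 224)
    c_gen: int = 20
    c_critic: int = 16
    latent_dim: int = LATENT_DIM
    mapping_layers: int = 8
    eq_lr: bool = True

    def __post_init__(self):
        self.grid = tuple(int(g) for g in self.grid)
        if any(g % 32 for g in self.grid):
            raise ValueError(f"grid extents must be divisible by 32, got {self.grid}")

    @property
    def base_grid(self) -> tuple:
        return tuple(g // 32 for g in self.grid)


@dataclass
class StageState:
    """Progressive-growing position: current stage and fade-in blend weight."""

    stage: int
    fade_alpha: float = 1.0

    def __post_init__(self):
        if self.stage not in range(1, N_STAGES + 1):
            raise ValueError(f"stage must be in 1..{N_STAGES}, got {self.stage}")
        if not 0.0 <= self.fade_alpha <= 1.0:
            raise ValueError("fade_alpha must lie in [0, 1]")


def channel_schedule(c: int) -> tuple:
    """Stage channel widths ``(8c, 8c, 4c, 2c, c)`` for stages 1..5."""
    return (8 * c, 8 * c, 4 * c, 2 * c, c)


def stage_resolution(cfg: ModelConfig, stage: int) -> tuple:
    """Spatial extent of the stage-``stage`` image: ``grid / 2**(5 - stage)``."""
    f = 2 ** (N_STAGES - stage)
    return tuple(g // f for g in cfg.grid)


def sample_latent(n: int, rng: np.random.Generator, dim: int = LATENT_DIM) -> np.ndarray:
    """``n`` i.i.d. standard-normal latent codes, shape ``(n, dim)``."""
    if n < 1:
        raise ValueError("need n >= 1 latent draws")
    return rng.standard_normal((n, dim)).astype(np.float32)


def avgpool2(x: Tensor) -> Tensor:
    """2x2x2 average pooling (the critic-side downsampling)."""
    return ad.blocksum2(x) * 0.125


# ---------------------------------------------------------------------------
# progressive generator
# ---------------------------------------------------------------------------

class _ProGANBlock(Module):
    def __init__(self, c_in, c_out, rng, eq_lr):
        self.conv1 = Conv3(c_in, c_out, rng, eq_lr=eq_lr)
        self.conv2 = Conv3(c_out, c_out, rng, eq_lr=eq_lr)

    def __call__(self, x):
        x = pixel_norm(ad.leaky_relu(self.conv1(ad.upsample2(x))))
        return pixel_norm(ad.leaky_relu(self.conv2(x)))


class ProGANGenerator(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        sched = channel_schedule(cfg.c_gen)
        base_vox = int(np.prod(cfg.base_grid))
        self.dense = Dense(cfg.latent_dim, sched[0] * base_vox, rng, eq_lr=cfg.eq_lr)
        self.blocks = []
        c_prev = sched[0]
        for k in range(N_STAGES):
            self.blocks.append(_ProGANBlock(c_prev, sched[k], rng, cfg.eq_lr))
            c_prev = sched[k]
        self.to_image = [Conv1x1(sched[k], 1, rng, gain=1.0, eq_lr=cfg.eq_lr)
                         for k in range(N_STAGES)]

    def first_linear_weight(self) -> np.ndarray:
        """Effective weight of the first dense layer, rows = outputs.

        This is the matrix whose principal right-singular directions define
        the closed-form latent attribute directions.
        """
        return self.dense.effective_weight()

    def __call__(self, z, state: StageState) -> Tensor:
        z = ad.as_tensor(z)
        sched = channel_schedule(self.cfg.c_gen)
        x = pixel_norm(ad.leaky_relu(self.dense(z)))
        x = ad.reshape(x, (z.shape[0], sched[0]) + self.cfg.base_grid)
        prev = None
        for k in range(state.stage):
            prev = x
            x = self.blocks[k](x)
        img = self.to_image[state.stage - 1](x)
        if state.stage > 1 and state.fade_alpha < 1.0:
            old = ad.upsample2(self.to_image[state.stage - 2](prev))
            img = state.fade_alpha * img + (1.0 - state.fade_alpha) * old
        return img


# ---------------------------------------------------------------------------
# style-based generator
# ---------------------------------------------------------------------------

class MappingNetwork(Module):
    """Fully connected ``z -> w`` map (leaky-ReLU MLP, 512 -> 512)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 eq_lr: bool | None = None):
        eq_lr = cfg.eq_lr if eq_lr is None else eq_lr
        self.layers = [Dense(cfg.latent_dim, cfg.latent_dim, rng, eq_lr=eq_lr)
                       for _ in range(cfg.mapping_layers)]

    def __call__(self, z) -> Tensor:
        x = ad.as_tensor(z)
        for layer in self.layers:
            x = ad.leaky_relu(layer(x))
        return x


def demodulated_conv(x: Tensor, w: Tensor, style: Tensor,
                     scale: float = 1.0, eps: float = 1e-8) -> Tensor:
    """Style-modulated 3x3x3 convolution with weight demodulation.

    Each input channel of the kernel is scaled by the style vector, then every
    output channel's composite kernel is renormalized to unit L2 norm.  The
    equivalent input-scaling form is used so a single (unmodulated) convolution
    serves the whole batch.  The output is invariant to a positive rescaling
    of ``style`` by construction.
    """
    x, w, style = ad.as_tensor(x), ad.as_tensor(w), ad.as_tensor(style)
    B, ci = style.shape
    xs = x * ad.reshape(style, (B, ci, 1, 1, 1))
    y = ad.conv3d(xs, w, stride=1, pad=1) * scale
    w2 = ad.tsum((w * scale) ** 2.0, axis=(2, 3, 4))          # (O, I)
    sigma2 = ad.matmul(style ** 2.0, ad.transpose(w2, (1, 0)))  # (B, O)
    d = 1.0 / ad.sqrt(sigma2 + eps)
    return y * ad.reshape(d, (B, w.shape[0], 1, 1, 1))


def inject_noise(x: Tensor, scale: Tensor, noise: np.ndarray) -> Tensor:
    """Add one spatial noise map, scaled by a learnable scalar, to every
    feature map (the same realization across channels)."""
    return x + scale * Tensor(noise)


class _StyledConv(Module):
    def __init__(self, c_in, c_out, latent_dim, rng, eq_lr):
        fan_in = c_in * 27
        if eq_lr:
            self.scale = float(np.sqrt(2.0) / np.sqrt(fan_in))
            w = rng.standard_normal((c_out, c_in, 3, 3, 3))
        else:
            self.scale = 1.0
            w = rng.standard_normal((c_out, c_in, 3, 3, 3)) * np.sqrt(2.0 / fan_in)
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(c_out))
        # affine style head; bias 1 so an untrained head is a unit style
        self.style = Dense(latent_dim, c_in, rng, gain=1.0, eq_lr=eq_lr, bias_init=1.0)
        self.noise_scale = Parameter(np.zeros(()))

    def __call__(self, x, style_code, noise):
        y = demodulated_conv(x, self.w, style_code, self.scale)
        y = y + ad.reshape(self.b, (1, -1, 1, 1, 1))
        if noise is not None:
            y = inject_noise(y, self.noise_scale, noise)
        return ad.leaky_relu(y)


class StyleSynthesis(Module):
    """The styled half ``G~: W -> X``: constant input, 15 styled convolutions
    (three per stage, the first following the upsampling), per-stage to-image
    convolutions for progressive fade-in."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        sched = channel_schedule(cfg.c_gen)
        self.const = Parameter(rng.standard_normal((sched[0],) + cfg.base_grid))
        self.convs = []
        c_prev = sched[0]
        for k in range(N_STAGES):
            c_out = sched[k]
            self.convs.append(_StyledConv(c_prev, c_out, cfg.latent_dim, rng, cfg.eq_lr))
            self.convs.append(_StyledConv(c_out, c_out, cfg.latent_dim, rng, cfg.eq_lr))
            self.convs.append(_StyledConv(c_out, c_out, cfg.latent_dim, rng, cfg.eq_lr))
            c_prev = c_out
        self.to_image = [Conv1x1(sched[k], 1, rng, gain=1.0, eq_lr=cfg.eq_lr)
                         for k in range(N_STAGES)]

    def style_codes(self, w) -> list:
        """The 15 per-layer style vectors for intermediate latent ``w``."""
        w = ad.as_tensor(w)
        return [conv.style(w) for conv in self.convs]

    def style_matrix(self) -> np.ndarray:
        """Row-stacked effective weights of the 15 affine style heads
        (biases excluded) — the spectral-analysis matrix for closed-form
        direction discovery."""
        return np.vstack([c.style.effective_weight() for c in self.convs])

    def _noise_maps(self, batch, stage, rng):
        maps = []
        for k in range(stage):
            res = stage_resolution(self.cfg, k + 1)
            for _ in range(STYLES_PER_STAGE):
                if rng is None:
                    maps.append(None)
                else:
                    maps.append(rng.standard_normal((batch, 1) + res).astype(np.float32))
        return maps

    def __call__(self, styles: list, state: StageState,
                 rng: np.random.Generator | None = None,
                 noise_maps: list | None = None) -> Tensor:
        if len(styles) != N_STYLES:
            raise ValueError(f"need {N_STYLES} style codes, got {len(styles)}")
        B = styles[0].shape[0]
        if noise_maps is None:
            noise_maps = self._noise_maps(B, state.stage, rng)
        x = ad.broadcast_to(ad.reshape(self.const, (1,) + self.const.shape),
                            (B,) + self.const.shape)
        prev = None
        for k in range(state.stage):
            prev = x
            x = ad.upsample2(x)
            for j in range(STYLES_PER_STAGE):
                li = k * STYLES_PER_STAGE + j
                x = self.convs[li](x, styles[li], noise_maps[li])
        img = self.to_image[state.stage - 1](x)
        if state.stage > 1 and state.fade_alpha < 1.0:
            old = ad.upsample2(self.to_image[state.stage - 2](prev))
            img = state.fade_alpha * img + (1.0 - state.fade_alpha) * old
        return img


class StyleGenerator(Module):
    """``G = G~ o phi``: mapping network plus styled synthesis."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.mapping = MappingNetwork(cfg, rng)
        self.synthesis = StyleSynthesis(cfg, rng)

    def __call__(self, z, state: StageState,
                 rng: np.random.Generator | None = None) -> Tensor:
        w = self.mapping(z)
        return self.forward_w(w, state, rng=rng)

    def forward_w(self, w, state: StageState,
                  rng: np.random.Generator | None = None,
                  noise_maps: list | None = None,
                  style_override: dict | None = None) -> Tensor:
        """Synthesis from an intermediate latent, with optional per-layer
        style substitution (``{layer_index: code}``) for mixing."""
        styles = self.synthesis.style_codes(w)
        if style_override:
            for idx, code in style_override.items():
                styles[idx] = ad.as_tensor(code)
        return self.synthesis(styles, state, rng=rng, noise_maps=noise_maps)


# ---------------------------------------------------------------------------
# critic
# ---------------------------------------------------------------------------

class Critic(Module):
    """Patch critic: per stage a 1x1x1 from-image convolution, then the
    remaining strided 3x3x3 convolutions of the full five-layer stack, and a
    1x1x1 score convolution averaged into one scalar per sample."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        sched = channel_schedule(cfg.c_critic)   # width at each stage's resolution
        widths = list(sched)                      # widths[k-1] = input width at stage k
        deepest = sched[0]                        # 8c at the coarsest grid
        self.from_image = [Conv1x1(1, widths[k], rng, eq_lr=cfg.eq_lr)
                           for k in range(N_STAGES)]
        # strided[k] downsamples from stage-(k+1) resolution to stage-k resolution
        self.strided = []
        for k in range(N_STAGES):
            c_in = widths[k]
            c_out = widths[k - 1] if k > 0 else deepest
            self.strided.append(Conv3(c_in, c_out, rng, stride=2, eq_lr=cfg.eq_lr))
        self.score = Conv1x1(deepest, 1, rng, gain=1.0, eq_lr=cfg.eq_lr)

    def features(self, v, state: StageState) -> Tensor:
        """Activations entering the score convolution (the penultimate layer
        used as the perceptual feature map)."""
        v = ad.as_tensor(v)
        expected = stage_resolution(self.cfg, state.stage)
        if tuple(v.shape[2:]) != expected:
            raise ValueError(f"stage {state.stage} expects input {expected}, "
                             f"got {tuple(v.shape[2:])}")
        x = ad.leaky_relu(self.from_image[state.stage - 1](v))
        for k in range(state.stage - 1, -1, -1):
            x = ad.leaky_relu(self.strided[k](x))
            if k == state.stage - 1 and state.stage > 1 and state.fade_alpha < 1.0:
                old = ad.leaky_relu(self.from_image[state.stage - 2](avgpool2(v)))
                x = state.fade_alpha * x + (1.0 - state.fade_alpha) * old
        return x

    def __call__(self, v, state: StageState) -> Tensor:
        x = self.features(v, state)
        s = self.score(x)
        return ad.tmean(s, axis=(1, 2, 3, 4))    # (B,) patch-mean scores


# ---------------------------------------------------------------------------
# encoder (GAN inversion)
# ---------------------------------------------------------------------------

class Encoder(Module):
    """Reversed generator mapping an image to a 512-dim code.

    Pixel feature normalization is deliberately absent.  The style variant
    appends two fully connected leaky-ReLU layers.
    """

    uses_pixel_norm = False

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 variant: str = "progan", stage: int = N_STAGES):
        if variant not in ("progan", "stylegan"):
            raise ValueError(f"unknown variant: {variant!r}")
        self.cfg = cfg
        self.variant = variant
        self.stage = stage
        sched = channel_schedule(cfg.c_gen)
        self.from_image = Conv1x1(1, sched[stage - 1], rng, eq_lr=cfg.eq_lr)
        self.blocks = []
        for k in range(stage - 1, -1, -1):
            c_in = sched[k]
            c_out = sched[k - 1] if k > 0 else sched[0]
            self.blocks.append(Conv3(c_in, c_in, rng, eq_lr=cfg.eq_lr))
            self.blocks.append(Conv3(c_in, c_out, rng, stride=2, eq_lr=cfg.eq_lr))
        # `stage` stride-2 stages take the input down to the base grid
        bottom_vox = int(np.prod(cfg.base_grid))
        self.head = Dense(sched[0] * bottom_vox, cfg.latent_dim, rng,
                          gain=1.0, eq_lr=cfg.eq_lr)
        if variant == "stylegan":
            self.fc_extra = [Dense(cfg.latent_dim, cfg.latent_dim, rng, eq_lr=cfg.eq_lr)
                             for _ in range(2)]
        else:
            self.fc_extra = []

    def __call__(self, v) -> Tensor:
        v = ad.as_tensor(v)
        expected = stage_resolution(self.cfg, self.stage)
        if tuple(v.shape[2:]) != expected:
            raise ValueError(f"encoder expects input {expected}, got {tuple(v.shape[2:])}")
        x = ad.leaky_relu(self.from_image(v))
        for block in self.blocks:
            x = ad.leaky_relu(block(x))
        B = x.shape[0]
        code = self.head(ad.reshape(x, (B, -1)))
        for fc in self.fc_extra:
            code = ad.leaky_relu(fc(code))
        return code


class LatentDiscriminator(Module):
    """512 -> (0, 1) classifier separating encoder codes from mapped codes."""

    def __init__(self, rng: np.random.Generator, latent_dim: int = LATENT_DIM):
        self.fc1 = Dense(latent_dim, 256, rng)
        self.fc2 = Dense(256, 128, rng)
        self.fc3 = Dense(128, 1, rng, gain=1.0)

    def __call__(self, code) -> Tensor:
        x = ad.leaky_relu(self.fc1(ad.as_tensor(code)))
        x = ad.leaky_relu(self.fc2(x))
        logit = self.fc3(x)
        return 1.0 / (1.0 + ad.exp(-logit))
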