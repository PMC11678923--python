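"""Hybrid GAN inversion: encoder initialization plus gradient refinement.

Learning-based inversion (an encoder) is fast but approximate; optimization
of the latent code is accurate but needs a good starting point.  The hybrid
scheme trains an encoder against a frozen generator and critic, then refines
each encoder code by a short Adam run on a reconstruction objective.

Loss terms (per image ``x``, encoder ``E``, generator ``G``, critic features
``phi`` = output of the critic layer before the score convolution):

* distortion      ``0.5 / #vox  * sum (x - G(E(x)))^2``
* perceptual      ``0.5 / #feat * sum (phi(x) - phi(G(E(x))))^2``
* plausibility    ``1/1024 * sum E(x)_r^2``        (progressive variant)
* adversarial     ``-1/512 * sum log D_W(E(x))``   (style variant)

The plausibility normalizations follow the printed constants verbatim —
``1/1024`` equals ``0.5/512`` for a 512-vector but is kept as written.  The
style-variant refinement objective is feature-matching only; a voxel term can
be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Adam
from .networks import (Critic, Encoder, LatentDiscriminator, StageState,
                       sample_latent)

__all__ = [
    "InversionResult", "EncoderTrainConfig",
    "distortion_loss", "perceptual_loss", "latent_plausibility_loss",
    "latent_adversarial_loss", "encoder_objective",
    "train_encoder", "refinement_objective", "refine_latent", "invert",
]

_LOG_EPS = 1e-8       # clamp inside the adversarial log
_LATENT_DIM = 512


@dataclass
class InversionResult:
    code: np.ndarray
    reconstruction: np.ndarray
    loss_terms: dict
    iterations: int
    objective: float


@dataclass
class EncoderTrainConfig:
    steps: int = 200
    batch: int = 4
    lr: float = 3e-3
    betas: tuple = (0.5, 0.9)
    seed: int = 0


# ---------------------------------------------------------------------------
# loss terms (operate on autodiff tensors; callables keep them testable
# against brute-force oracles with toy encoders/generators)
# ---------------------------------------------------------------------------

def distortion_loss(x, encoder, generator) -> Tensor:
    """Half mean squared voxel error between ``x`` and ``G(E(x))``."""
    x = ad.as_tensor(x)
    recon = generator(encoder(x))
    diff = x - recon
    return 0.5 * ad.tmean(diff * diff)


def perceptual_loss(x, encoder, generator, features) -> Tensor:
    """Half mean squared error of penultimate critic features."""
    x = ad.as_tensor(x)
    recon = generator(encoder(x))
    fx, fr = features(x), features(recon)
    diff = fx - fr
    return 0.5 * ad.tmean(diff * diff)


def latent_plausibility_loss(x, encoder) -> Tensor:
    """``(1/1024) * sum_r E(x)_r^2`` (mean over the batch)."""
    code = encoder(ad.as_tensor(x))
    if code.shape[-1] != _LATENT_DIM:
        raise ValueError(f"expected a {_LATENT_DIM}-dim code, got {code.shape[-1]}")
    per_sample = ad.tsum(code * code, axis=-1) * (1.0 / 1024.0)
    return ad.tmean(per_sample)


def latent_adversarial_loss(x, encoder, discriminator) -> Tensor:
    """``-(1/512) * sum_r log D_W(E(x))``.

    The discriminator output is a scalar per sample; the printed sum over
    512 broadcast copies collapses to ``-log D_W(E(x))``.  Outputs are
    clamped at ``1e-8`` before the log.
    """
    code = encoder(ad.as_tensor(x))
    d = discriminator(code)
    return -ad.tmean(ad.log(ad.clip(d, _LOG_EPS, None)))


def encoder_objective(x, encoder, generator, features, variant: str,
                      discriminator=None) -> tuple:
    """The variant's risk and its named terms.

    progressive: ``dist + perc + latent``; style: ``5*dist + perc + 0.04*lW``.
    The encoder code and reconstruction are computed once and shared by all
    terms (the weighted sums match the individual loss functions exactly).
    """
    x = ad.as_tensor(x)
    code = encoder(x)
    recon = generator(code)
    diff = x - recon
    dist = 0.5 * ad.tmean(diff * diff)
    fd = features(x) - features(recon)
    perc = 0.5 * ad.tmean(fd * fd)
    if variant == "progan":
        lat = ad.tmean(ad.tsum(code * code, axis=-1)) * (1.0 / 1024.0)
        total = dist + perc + lat
        terms = {"dist": dist, "perc": perc, "latent": lat}
    elif variant == "stylegan":
        if discriminator is None:
            raise ValueError("style variant needs the latent discriminator")
        lw = -ad.tmean(ad.log(ad.clip(discriminator(code), _LOG_EPS, None)))
        total = 5.0 * dist + perc + 0.04 * lw
        terms = {"dist": dist, "perc": perc, "latent_adv": lw}
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    return total, terms


# ---------------------------------------------------------------------------
# encoder training
# ---------------------------------------------------------------------------

def train_encoder(data: np.ndarray, generator, critic: Critic,
                  model_cfg, stage: int, variant: str = "progan",
                  cfg: EncoderTrainConfig | None = None, mapping=None):
    """Fit an encoder against a frozen generator/critic pair.

    ``generator`` is a callable ``code -> image tensor`` already bound to a
    stage (a latent code for the progressive variant, an intermediate latent
    for the style variant).  For the style variant, ``mapping`` must be the
    trained mapping network; a latent discriminator is then trained
    alternately on mapped codes (real) versus encoder codes (fake).
    Returns ``(encoder, discriminator_or_None, history)``.
    """
    if generator is None or critic is None:
        raise ValueError("encoder training needs a pretrained generator and critic")
    if variant == "stylegan" and mapping is None:
        raise ValueError("style-variant encoder training needs the mapping network")
    cfg = cfg or EncoderTrainConfig()
    data = np.asarray(data, dtype=np.float32)
    root = np.random.SeedSequence(cfg.seed)
    ss_init, ss_batch = root.spawn(2)
    init_rng = np.random.default_rng(ss_init)
    rng = np.random.default_rng(ss_batch)

    state = StageState(stage)
    E = Encoder(model_cfg, init_rng, variant=variant, stage=stage)
    opt = Adam(E.parameters(), lr=cfg.lr, betas=cfg.betas)
    features = lambda v: critic.features(v, state)

    Dw, opt_d = None, None
    if variant == "stylegan":
        Dw = LatentDiscriminator(init_rng, model_cfg.latent_dim)
        opt_d = Adam(Dw.parameters(), lr=cfg.lr, betas=cfg.betas)

    history = []
    e_params = E.parameters()
    gen_fn = generator
    for step in range(cfg.steps):
        idx = rng.integers(0, data.shape[0], size=cfg.batch)
        x = Tensor(data[idx][:, None])

        if variant == "stylegan":
            # discriminator update: mapped codes real, encoder codes fake
            z = sample_latent(cfg.batch, rng, model_cfg.latent_dim)
            with ad.no_grad():
                real_codes = mapping(z).data
                fake_codes = E(x).data
            d_real = Dw(Tensor(real_codes))
            d_fake = Dw(Tensor(fake_codes))
            loss_d = -ad.tmean(ad.log(ad.clip(d_real, _LOG_EPS, None))) \
                     - ad.tmean(ad.log(ad.clip(1.0 - d_fake, _LOG_EPS, None)))
            opt_d.step(ad.grad(loss_d, Dw.parameters()))

        total, terms = encoder_objective(x, E, gen_fn, features, variant, Dw)
        opt.step(ad.grad(total, e_params))
        history.append({"step": step, "loss": float(total.data),
                        **{k: float(v.data) for k, v in terms.items()}})
    return E, Dw, history


# ---------------------------------------------------------------------------
# per-image refinement
# ---------------------------------------------------------------------------

def refinement_objective(x, code, generator, features, variant: str,
                         include_voxel_term: bool = False,
                         target_features: Tensor | None = None) -> Tensor:
    """The refinement objective for one image.

    progressive: ``(1/#vox)||x - G(z)||^2 + (1/#feat)||phi(x) - phi(G(z))||^2
    + (1/512)||z||^2``.  style: feature term only (optionally plus the voxel
    term).  ``target_features`` may carry precomputed ``phi(x)`` (it is
    constant across refinement iterations).
    """
    x = ad.as_tensor(x)
    recon = generator(code)
    diff = x - recon
    vox_term = ad.tmean(diff * diff)
    fx = target_features if target_features is not None else features(x)
    fd = fx - features(recon)
    feat_term = ad.tmean(fd * fd)
    if variant == "progan":
        return vox_term + feat_term + ad.tsum(code * code) / float(_LATENT_DIM)
    if variant == "stylegan":
        return feat_term + vox_term if include_voxel_term else feat_term
    raise ValueError(f"unknown variant: {variant!r}")


def refine_latent(x, init_code, generator, features, variant: str = "progan",
                  steps: int = 100, lr: float = 7e-3,
                  include_voxel_term: bool = False) -> InversionResult:
    """Adam refinement of a latent code; returns the best-seen iterate.

    ``generator`` maps a (1, 512) code tensor to an image tensor, ``features``
    an image tensor to critic features.  Divergence (non-finite objective)
    raises with the iteration index.
    """
    x = ad.as_tensor(x)
    code = Tensor(np.asarray(init_code, dtype=np.float32).reshape(1, -1),
                  requires_grad=True)
    opt = Adam([code], lr=lr, betas=(0.9, 0.999))
    with ad.no_grad():
        fx = features(x).detach()

    def evaluate():
        return refinement_objective(x, code, generator, features, variant,
                                    include_voxel_term, target_features=fx)

    with ad.no_grad():
        best_obj = float(evaluate().data)
    best_code = code.data.copy()

    for it in range(steps):
        obj = evaluate()
        val = float(obj.data)
        if not np.isfinite(val):
            raise FloatingPointError(f"refinement diverged at iteration {it}")
        if val < best_obj:
            best_obj, best_code = val, code.data.copy()
        opt.step(ad.grad(obj, [code]))

    with ad.no_grad():
        code.data = best_code
        recon = generator(code)
        diff = (x - recon)
        terms = {
            "dist": float(ad.tmean(diff * diff).data),
            "perc": float(ad.tmean((features(x) - features(recon)) ** 2.0).data),
            "latent": float((best_code ** 2).sum() / _LATENT_DIM),
        }
    return InversionResult(code=best_code[0], reconstruction=recon.data[0, 0],
                           loss_terms=terms, iterations=steps, objective=best_obj)


def invert(x, encoder: Encoder, generator, features,
           variant: str = "progan", **refine_kwargs) -> InversionResult:
    """Hybrid inversion: encoder initial guess, then gradient refinement."""
    x = ad.as_tensor(x)
    with ad.no_grad():
        init = encoder(x).data
    return refine_latent(x, init, generator, features, variant, **refine_kwargs)
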