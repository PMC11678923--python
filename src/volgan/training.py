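"""Wasserstein training with two-sided gradient penalty and progressive growing.

The critic minimizes ``E[f(G(z)) - f(x)] + p1 * (||grad f(x~)|| - 1)^2
+ p2 * f(x)^2`` where ``x~`` is a per-sample uniform interpolation between a
real and a generated volume; the generator minimizes ``-E[f(G(z))]``.  Both
use Adam, alternating ``n_critic`` critic updates per generator update.

Stages grow from coarse to fine with a linear fade-in of the new layers over
the first ``fade_fraction`` of each stage's update budget.  Roughly 10% of the
training stacks are held out; the critic's real-fake gap on that split is
logged as an overfitting diagnostic, never used for updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Adam
from .networks import (Critic, ModelConfig, ProGANGenerator, StageState,
                       StyleGenerator, sample_latent, stage_resolution)

__all__ = ["TrainConfig", "TrainResult", "gradient_penalty", "critic_loss",
           "generator_loss", "train", "downsample_pyramid"]


@dataclass
class TrainConfig:
    p1: float = 10.0               # gradient-penalty weight
    p2: float = 0.001              # drift-penalty weight
    lr: float = 4e-3               # Adam alpha
    betas: tuple = (0.0, 0.99)
    n_critic: int = 5              # critic iterations per generator update
    stage_cap: int = 5
    steps_per_stage: tuple = (50, 50, 50, 50, 50)   # generator updates per stage
    batch_per_stage: tuple = (16, 16, 8, 4, 2)      # halving as resolution grows
    fade_fraction: float = 0.5
    val_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> "TrainConfig":
        if self.p1 < 0 or self.p2 < 0:
            raise ValueError("penalty weights must be non-negative")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if len(self.steps_per_stage) < self.stage_cap or \
                len(self.batch_per_stage) < self.stage_cap:
            raise ValueError("need a step and batch entry for every stage")
        return self


@dataclass
class TrainResult:
    generator: object
    critic: Critic
    history: list
    train_indices: np.ndarray
    val_indices: np.ndarray
    initial_generator_state: dict
    counters: dict


def gradient_penalty(critic_fn, real, fake, rng: np.random.Generator) -> Tensor:
    """Two-sided gradient penalty ``mean((||grad_x f(x~)||_2 - 1)^2)``.

    ``critic_fn`` maps a (B, 1, D, H, W) tensor to per-sample scores (B,).
    ``x~`` interpolates real and fake with a per-sample uniform weight.
    """
    real = np.asarray(real.data if isinstance(real, Tensor) else real)
    fake = np.asarray(fake.data if isinstance(fake, Tensor) else fake)
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must share a shape")
    B = real.shape[0]
    u = rng.random((B,) + (1,) * (real.ndim - 1)).astype(real.dtype)
    x = Tensor(u * real + (1.0 - u) * fake, requires_grad=True)
    total = ad.tsum(critic_fn(x))
    (gx,) = ad.grad(total, [x], create_graph=True)
    axes = tuple(range(1, real.ndim))
    norms = ad.sqrt(ad.tsum(gx * gx, axis=axes) + 1e-12)
    return ad.tmean((norms - 1.0) ** 2.0)


def critic_loss(critic_fn, real, fake, p1: float, p2: float,
                rng: np.random.Generator) -> Tensor:
    """Full critic objective: Wasserstein term + gradient and drift penalties."""
    real_t, fake_t = ad.as_tensor(real), ad.as_tensor(fake)
    f_real = critic_fn(real_t)
    f_fake = critic_fn(fake_t)
    loss = ad.tmean(f_fake) - ad.tmean(f_real)
    if p1:
        loss = loss + p1 * gradient_penalty(critic_fn, real_t, fake_t, rng)
    if p2:
        loss = loss + p2 * ad.tmean(f_real * f_real)
    return loss


def generator_loss(critic_fn, fake) -> Tensor:
    """``-E[f(G(z))]`` on an already generated batch."""
    return -ad.tmean(critic_fn(ad.as_tensor(fake)))


def downsample_pyramid(data: np.ndarray, levels: int) -> list:
    """Block-mean pyramid; entry ``i`` is ``data`` pooled ``i`` times by 2."""
    out = [data.astype(np.float32)]
    cur = out[0]
    for _ in range(levels):
        D, H, W = cur.shape[1:]
        cur = cur.reshape(-1, D // 2, 2, H // 2, 2, W // 2, 2).mean(axis=(2, 4, 6))
        out.append(cur.astype(np.float32))
    return out


def _fade_alpha(step: int, total: int, fade_fraction: float) -> float:
    if fade_fraction <= 0:
        return 1.0
    ramp = max(int(round(fade_fraction * total)), 1)
    return min(1.0, (step + 1) / ramp)


def train(data: np.ndarray, cfg: TrainConfig, model_cfg: ModelConfig,
          model: str = "progan") -> TrainResult:
    """Train a progressive or style-based generator on fixed-shape stacks.

    ``data`` has shape (N, D, H, W) matching the stage-``stage_cap``
    resolution of ``model_cfg``.  Returns the trained networks, the per-update
    log, the train/validation split and a snapshot of the generator's initial
    parameters (useful for before/after comparisons).
    """
    cfg.validate()
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 4 or data.shape[0] < 2:
        raise ValueError("data must be a non-empty (N, D, H, W) stack array")
    expected = stage_resolution(model_cfg, cfg.stage_cap)
    if data.shape[1:] != expected:
        raise ValueError(f"stacks must be at stage-{cfg.stage_cap} resolution "
                         f"{expected}, got {data.shape[1:]}")

    root = np.random.SeedSequence(cfg.seed)
    ss_init, ss_split, ss_train, ss_eval = root.spawn(4)
    init_rng = np.random.default_rng(ss_init)
    rng = np.random.default_rng(ss_train)
    eval_rng = np.random.default_rng(ss_eval)

    # held-out split for critic-overfitting diagnostics
    perm = np.random.default_rng(ss_split).permutation(data.shape[0])
    n_val = max(int(round(cfg.val_fraction * data.shape[0])), 1)
    val_idx, train_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])
    if train_idx.size == 0:
        raise ValueError("validation split consumed all the data")

    pyramids = downsample_pyramid(data, cfg.stage_cap - 1)
    # pyramids[i] pooled i times: stage s uses level stage_cap - s

    if model == "progan":
        G = ProGANGenerator(model_cfg, init_rng)
    elif model == "stylegan":
        G = StyleGenerator(model_cfg, init_rng)
    else:
        raise ValueError(f"unknown model: {model!r}")
    C = Critic(model_cfg, init_rng)
    g_params, c_params = G.parameters(), C.parameters()
    opt_g = Adam(g_params, lr=cfg.lr, betas=cfg.betas)
    opt_c = Adam(c_params, lr=cfg.lr, betas=cfg.betas)

    initial_state = G.state_dict()
    history: list = []
    counters = {"critic_updates": 0, "generator_updates": 0}
    z_eval = sample_latent(4, eval_rng, model_cfg.latent_dim)

    def g_forward(z, state):
        if model == "stylegan":
            return G(z, state, rng=rng)
        return G(z, state)

    for stage in range(1, cfg.stage_cap + 1):
        steps = cfg.steps_per_stage[stage - 1]
        batch = cfg.batch_per_stage[stage - 1]
        level = cfg.stage_cap - stage
        reals = pyramids[level]
        train_pool = reals[train_idx]
        val_pool = reals[val_idx]

        for step in range(steps):
            alpha = _fade_alpha(step, steps, cfg.fade_fraction) if stage > 1 else 1.0
            state = StageState(stage, alpha)
            critic_fn = lambda v: C(v, state)

            for _ in range(cfg.n_critic):
                idx = rng.integers(0, train_pool.shape[0], size=batch)
                real = train_pool[idx][:, None]
                z = sample_latent(batch, rng, model_cfg.latent_dim)
                with ad.no_grad():
                    fake = g_forward(z, state).data
                loss_c = critic_loss(critic_fn, real, fake, cfg.p1, cfg.p2, rng)
                grads = ad.grad(loss_c, c_params)
                opt_c.step(grads)
                counters["critic_updates"] += 1

            z = sample_latent(batch, rng, model_cfg.latent_dim)
            fake = g_forward(z, state)
            loss_g = generator_loss(critic_fn, fake)
            grads = ad.grad(loss_g, g_params)
            opt_g.step(grads)
            counters["generator_updates"] += 1

            with ad.no_grad():
                vb = val_pool[:min(len(val_pool), 8), None]
                f_val = C(Tensor(vb), state).data.mean()
                f_gen = C(g_forward(z_eval, state), state).data.mean()
            history.append({
                "stage": stage, "step": step, "fade_alpha": alpha,
                "critic_loss": float(loss_c.data), "gen_loss": float(loss_g.data),
                "val_gap": float(f_val - f_gen),
            })

    return TrainResult(G, C, history, train_idx, val_idx, initial_state, counters)
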