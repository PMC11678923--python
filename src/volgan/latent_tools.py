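"""Latent-space semantics: truncation, transitions, style mixing, closed-form
attribute directions and editing.

Direction discovery follows the spectral recipe: the unit vector maximizing
``||A n||^2`` is the principal right-singular vector of ``A``, where ``A`` is
the first dense layer of the progressive generator or the row-stacked 15
affine style heads of the style generator.  The top-k directions are the
eigenvectors of ``A^T A`` with the largest eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import autodiff as ad
from .autodiff import Tensor
from .networks import (LATENT_DIM, N_STYLES, StageState, StyleGenerator,
                       sample_latent)

__all__ = [
    "Direction", "TruncationConfig",
    "truncated_normal", "mean_latent", "truncate_style",
    "transition", "style_mix", "find_directions", "edit",
]


@dataclass
class Direction:
    """A unit latent direction with its spectrum value and order index."""

    n: np.ndarray
    eigenvalue: float
    rank: int

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=np.float64)
        norm = np.linalg.norm(self.n)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError(f"direction must be unit length, got ||n||={norm}")


@dataclass
class TruncationConfig:
    progan_level: float = 1.8      # truncated-normal bound for z sampling
    style_psi: float = 0.8         # shrinkage toward the mean latent
    mean_latent_samples: int = 4096

    def __post_init__(self):
        if self.progan_level <= 0:
            raise ValueError("truncation level must be positive")
        if not 0.0 <= self.style_psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")


def truncated_normal(n: int, level: float = 1.8,
                     rng: np.random.Generator | None = None,
                     dim: int = LATENT_DIM) -> np.ndarray:
    """Per-coordinate standard normal conditioned on ``|value| <= level``,
    sampled by exact rejection."""
    if level <= 0:
        raise ValueError("truncation level must be positive")
    rng = rng or np.random.default_rng()
    out = rng.standard_normal((n, dim))
    bad = np.abs(out) > level
    while bad.any():
        out[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(out) > level
    return out.astype(np.float32)


def mean_latent(mapping, n: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo estimate of the average intermediate latent ``E[phi(z)]``."""
    if n < 1:
        raise ValueError("need n >= 1 samples")
    z = sample_latent(n, rng)
    with ad.no_grad():
        w = mapping(Tensor(z)).data
    return w.mean(axis=0)


def truncate_style(w: np.ndarray, w_mean: np.ndarray, psi: float = 0.8) -> np.ndarray:
    """Affine shrinkage ``w_mean + psi * (w - w_mean)``.

    The endpoints are short-circuited so ``psi=1`` returns ``w`` and ``psi=0``
    returns ``w_mean`` exactly (no floating-point round trip).
    """
    if not 0.0 <= psi <= 1.0:
        raise ValueError("psi must lie in [0, 1]")
    w, w_mean = np.asarray(w), np.asarray(w_mean)
    if psi == 1.0:
        return w.copy()
    if psi == 0.0:
        return w_mean.copy()
    return w_mean + psi * (w - w_mean)


def transition(generate, z1: np.ndarray, z2: np.ndarray, alphas) -> list:
    """Images along the latent segment: ``G(a * z1 + (1 - a) * z2)``.

    ``generate`` maps a (1, 512) code array to a volume array; outputs are
    ordered like ``alphas``.  At the endpoints the blended code equals one of
    the inputs exactly, so the images match plain generation bit for bit.
    """
    z1 = np.asarray(z1, dtype=np.float32).reshape(1, -1)
    z2 = np.asarray(z2, dtype=np.float32).reshape(1, -1)
    out = []
    for a in alphas:
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"transition weight must lie in [0, 1], got {a}")
        a32 = np.float32(a)
        code = a32 * z1 + (np.float32(1.0) - a32) * z2
        out.append(generate(code))
    return out


def style_mix(style_gen: StyleGenerator, ws: np.ndarray, wt: np.ndarray,
              cut: int, state: StageState) -> np.ndarray:
    """Generate with styles of ``ws`` in the first ``cut`` styled convolutions
    and styles of ``wt`` in the remaining ones.  Noise injections are frozen
    at zero so the mix is a deterministic function of the two codes."""
    if not 0 <= cut <= N_STYLES:
        raise ValueError(f"cut must lie in 0..{N_STYLES}, got {cut}")
    ws = Tensor(np.asarray(ws, dtype=np.float32).reshape(1, -1))
    wt = Tensor(np.asarray(wt, dtype=np.float32).reshape(1, -1))
    with ad.no_grad():
        styles_s = style_gen.synthesis.style_codes(ws)
        styles_t = style_gen.synthesis.style_codes(wt)
        styles = [styles_s[i] if i < cut else styles_t[i] for i in range(N_STYLES)]
        img = style_gen.synthesis(styles, state, rng=None)
    return img.data[0, 0]


def find_directions(A: np.ndarray, k: int = 4) -> list:
    """Top-``k`` right-singular directions of ``A`` (512 columns).

    Directions are unit-norm eigenvectors of ``A^T A`` ordered by decreasing
    eigenvalue, signs fixed so the first non-zero component is positive.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.shape[1] > 0 and k > A.shape[1]:
        raise ValueError(f"k={k} exceeds the latent dimension {A.shape[1]}")
    _, s, vt = scipy.linalg.svd(A, full_matrices=False)
    dirs = []
    for rank in range(k):
        v = vt[rank]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
        dirs.append(Direction(n=v, eigenvalue=float(s[rank] ** 2), rank=rank))
    return dirs


def edit(generate, code: np.ndarray, direction: Direction,
         strength: float = 4.0) -> tuple:
    """Attribute manipulation ``G(code + strength * n)``.

    Returns ``(edited, difference)`` where ``difference = edited - original``
    is the residual volume used to visualize what the direction changes.
    """
    code = np.asarray(code, dtype=np.float32).reshape(1, -1)
    shifted = code + np.float32(strength) * direction.n.astype(np.float32)
    original = generate(code)
    edited = generate(shifted)
    return edited, edited - original
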