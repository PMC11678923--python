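"""Raw-scan preprocessing: variable-shape volumes to fixed-shape training stacks.

The pipeline mirrors how HR-pQCT acquisitions with a fixed axial slice count
but varying in-plane extents are turned into a homogeneous training set:

1. centre crop / mirror-pad every volume to one constant shape,
2. synthesise a matched noise volume by clipping the volume's discrete cosine
   coefficients to a tiny band and transforming back,
3. overwrite the padded voxels with that noise (mirror padding alone would
   duplicate bone structure at the borders; real borders contain scanner
   noise),
4. subsample by an integer factor,
5. cut overlapping axial slice stacks, and optionally
6. augment each stack by a random in-plane rotation and central zoom-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy import ndimage

from .volume import Volume

__all__ = [
    "PreprocConfig",
    "pad_crop",
    "dct_noise",
    "blend_padding",
    "subsample",
    "extract_stacks",
    "augment",
    "preprocess_pipeline",
]


@dataclass
class PreprocConfig:
    target_shape: tuple = (168, 576, 448)
    clip_bound: float = 0.001
    subsample_factor: int = 2
    stack_size: int = 32
    stack_count: int = 4
    angle_range: tuple = (-10.0, 10.0)
    zoom_range: tuple = (1.0, 1.15)
    augment: bool = True
    subsample_mode: str = "mean"

    def validate(self) -> "PreprocConfig":
        if self.clip_bound <= 0:
            raise ValueError("clip_bound must be positive")
        if self.stack_count < 1:
            raise ValueError("stack_count must be >= 1")
        axial = self.target_shape[0] // self.subsample_factor
        if self.stack_size > axial:
            raise ValueError("stack_size exceeds the subsampled axial extent")
        if self.zoom_range[0] < 1.0:
            raise ValueError("zoom factors below 1 would expose undefined borders")
        return self


def _center_slices(src: int, dst: int):
    """Crop slice and pad widths taking ``src`` to ``dst``, centred."""
    if src >= dst:
        lo = (src - dst) // 2
        return slice(lo, lo + dst), (0, 0)
    pad_lo = (dst - src) // 2
    return slice(0, src), (pad_lo, dst - src - pad_lo)


def pad_crop(v: Volume, target: tuple) -> tuple:
    """Centre crop or mirror-pad ``v`` to ``target`` shape.

    Padding reflects the volume symmetrically including the edge voxel.
    Returns the resized volume and a boolean mask flagging padded voxels.
    """
    data = v.data
    slices, pads = zip(*(_center_slices(s, t) for s, t in zip(data.shape, target)))
    cropped = data[slices[0], slices[1], slices[2]]
    out = np.pad(cropped, pads, mode="symmetric")
    mask = np.ones(cropped.shape, dtype=bool)
    mask = ~np.pad(mask, pads, mode="constant", constant_values=False)
    return Volume(out, v.spacing), mask


def dct_noise(v: Volume, clip_bound: float = 0.001) -> Volume:
    """Noise image with all orthonormal type-II cosine coefficients in
    ``[-clip_bound, clip_bound]`` (the volume's clipped spectrum)."""
    if clip_bound <= 0:
        raise ValueError("clip_bound must be positive")
    coeff = scipy.fft.dctn(v.data, type=2, norm="ortho")
    np.clip(coeff, -clip_bound, clip_bound, out=coeff)
    noise = scipy.fft.idctn(coeff, type=2, norm="ortho")
    return Volume(noise.astype(v.data.dtype, copy=False), v.spacing)


def blend_padding(padded: Volume, noise: Volume, pad_mask: np.ndarray) -> Volume:
    """Replace padded voxels by the noise image, elementwise."""
    if padded.shape != noise.shape or padded.shape != pad_mask.shape:
        raise ValueError("padded volume, noise volume and mask shapes must agree")
    out = np.where(pad_mask, noise.data, padded.data)
    return Volume(out, padded.spacing)


def subsample(v: Volume, factor: int, mode: str = "mean") -> Volume:
    """Reduce every extent by ``factor``; block-mean by default (anti-aliased),
    plain decimation with ``mode='stride'``."""
    if factor == 1:
        return Volume(v.data.copy(), v.spacing)
    d = v.data
    if any(s % factor for s in d.shape):
        raise ValueError(f"shape {d.shape} not divisible by factor {factor}")
    if mode == "stride":
        out = d[::factor, ::factor, ::factor].copy()
    elif mode == "mean":
        A, V, H = (s // factor for s in d.shape)
        out = d.reshape(A, factor, V, factor, H, factor).mean(axis=(1, 3, 5))
        out = out.astype(d.dtype, copy=False)
    else:
        raise ValueError(f"unknown subsample mode: {mode!r}")
    spacing = tuple(s * factor for s in v.spacing)
    return Volume(out, spacing)


def stack_offsets(axial: int, stack_size: int, stack_count: int) -> np.ndarray:
    """Evenly spaced, rounded stack start slices; endpoints anchored."""
    if stack_size > axial:
        raise ValueError("stack_size exceeds the axial extent")
    if stack_count == 1:
        return np.array([0])
    return np.round(np.linspace(0, axial - stack_size, stack_count)).astype(int)


def extract_stacks(v: Volume, stack_size: int, stack_count: int) -> list:
    """Cut ``stack_count`` overlapping axial sub-volumes of ``stack_size`` slices."""
    offs = stack_offsets(v.shape[0], stack_size, stack_count)
    return [Volume(v.data[o:o + stack_size].copy(), v.spacing) for o in offs]


def augment(stack: Volume, angle_range=(-10.0, 10.0), zoom_range=(1.0, 1.15),
            rng: np.random.Generator | None = None, order: int = 1) -> Volume:
    """In-plane rotation about the axial axis followed by a central zoom-in.

    The angle (degrees) and zoom factor are uniform over the given ranges; the
    output keeps the input shape.  Zoom factors below 1 are rejected since a
    zoom-out would expose voxels with no defined content.
    """
    if zoom_range[0] < 1.0:
        raise ValueError("zoom factors must be >= 1")
    rng = rng or np.random.default_rng()
    angle = np.deg2rad(rng.uniform(*angle_range))
    zoom = rng.uniform(*zoom_range)

    c, s = np.cos(angle), np.sin(angle)
    # output -> input coordinate map: rotate by -angle, shrink by 1/zoom
    rot = np.array([[1.0, 0.0, 0.0],
                    [0.0, c, -s],
                    [0.0, s, c]]) / np.array([1.0, zoom, zoom])[None, :]
    center = (np.asarray(stack.shape) - 1) / 2.0
    offset = center - rot @ center
    out = ndimage.affine_transform(stack.data, rot, offset=offset, order=order,
                                   mode="nearest")
    return Volume(out.astype(stack.data.dtype, copy=False), stack.spacing)


def preprocess_pipeline(raw: Volume, cfg: PreprocConfig,
                        rng: np.random.Generator | None = None) -> list:
    """Full pipeline: pad/crop -> DCT noise -> blend -> subsample -> stacks
    (-> augment).  Deterministic when augmentation is disabled."""
    cfg.validate()
    padded, mask = pad_crop(raw, cfg.target_shape)
    if mask.any():
        noise = dct_noise(padded, cfg.clip_bound)
        blended = blend_padding(padded, noise, mask)
    else:
        blended = padded
    small = subsample(blended, cfg.subsample_factor, cfg.subsample_mode)
    stacks = extract_stacks(small, cfg.stack_size, cfg.stack_count)
    if cfg.augment:
        rng = rng or np.random.default_rng()
        stacks = [augment(s, cfg.angle_range, cfg.zoom_range, rng) for s in stacks]
    return stacks
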