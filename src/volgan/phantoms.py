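"""Procedural bone phantoms.

Real HR-pQCT scans of the distal radius show an annular high-intensity cortical
shell around a speckled trabecular interior, embedded in scanner background
noise, with 168 axial slices and in-plane extents that vary from scan to scan.
This module generates volumes with exactly those gross features from a compact
parametric description, so that every downstream stage — preprocessing, GAN
training, inversion, metrics — can be exercised end-to-end without patient
data.

Two intensity parameters act as analogues of the standard densitometric
read-outs: ``cortical_intensity`` for cortical bone mineral density (Ct.BMD)
and ``trabecular_fill`` (speckle occupancy) for trabecular BMD (Tb.BMD).
Motion-degraded acquisitions are emulated by shearing a contiguous block of
axial slices, the artifact that visual grading of HR-pQCT scans targets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import Volume

__all__ = [
    "PhantomSpec",
    "GradedVolume",
    "CohortRanges",
    "generate_phantom",
    "generate_cohort",
    "measure_density",
]

#: In-plane extent bounds observed across a distal-radius cohort (voxels).
VERTICAL_RANGE = (397, 663)
HORIZONTAL_RANGE = (278, 529)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic scan."""

    axial_slices: int = 168
    vertical_extent: int = 500
    horizontal_extent: int = 400
    cortical_thickness: float = 14.0   # shell thickness, voxels
    cortical_intensity: float = 0.8    # Ct.BMD analogue, grayscale in [0, 1]
    trabecular_fill: float = 0.3       # Tb.BMD analogue, occupancy fraction
    trabecular_intensity: float = 0.55
    noise_sd: float = 0.03             # background noise level (free choice)
    motion_artifact: bool = False
    motion_severity: int = 3           # in-plane shear of the moved block, voxels
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if min(self.axial_slices, self.vertical_extent, self.horizontal_extent) <= 0:
            raise ValueError("phantom extents must be positive")
        for name in ("cortical_intensity", "trabecular_intensity", "trabecular_fill"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        return self


@dataclass
class GradedVolume:
    """A volume plus its visual grading score, 1 (best) to 5 (worst)."""

    volume: Volume
    vgs: int

    def __post_init__(self):
        if self.vgs not in (1, 2, 3, 4, 5):
            raise ValueError(f"vgs must be in 1..5, got {self.vgs}")


@dataclass
class CohortRanges:
    """Sampling bounds for :func:`generate_cohort` (inclusive)."""

    vertical: tuple = VERTICAL_RANGE
    horizontal: tuple = HORIZONTAL_RANGE
    axial_slices: int = 168
    cortical_thickness: tuple = (8.0, 20.0)
    cortical_intensity: tuple = (0.55, 0.95)
    trabecular_fill: tuple = (0.15, 0.5)

    def validate(self) -> "CohortRanges":
        for name in ("vertical", "horizontal", "cortical_thickness",
                     "cortical_intensity", "trabecular_fill"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name}: [{lo}, {hi}]")
        return self


def _geometry(spec: PhantomSpec):
    """Deterministic phantom geometry: masks and the trabecular speckle.

    Returns ``(shell, interior, speckle)`` boolean arrays.  ``shell`` is the
    painted cortical annulus; with ``cortical_thickness == 0`` nothing is
    painted, but a one-voxel measurement band at the nominal shell position is
    still returned so that compartment means remain well defined.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x9e0]))
    A, V, H = spec.axial_slices, spec.vertical_extent, spec.horizontal_extent

    # smooth per-slice centre jitter: anatomical axis wobble
    jit = rng.normal(scale=1.0, size=(2, A))
    jit = gaussian_filter(jit, sigma=(0, 5), mode="nearest") * 3.0

    a = 0.38 * V   # vertical semi-axis
    b = 0.38 * H   # horizontal semi-axis
    yy = np.arange(V, dtype=np.float32)[None, :, None]
    xx = np.arange(H, dtype=np.float32)[None, None, :]
    cy = (V / 2.0 + jit[0])[:, None, None].astype(np.float32)
    cx = (H / 2.0 + jit[1])[:, None, None].astype(np.float32)
    rho = np.sqrt(((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2)

    r_eff = np.sqrt(a * b)
    t_paint = spec.cortical_thickness / r_eff
    t_meas = max(spec.cortical_thickness, 1.0) / r_eff

    shell_paint = (rho <= 1.0) & (rho >= 1.0 - t_paint)
    shell_meas = (rho <= 1.0) & (rho >= 1.0 - t_meas)
    interior = rho < 1.0 - t_paint

    noise = rng.normal(size=(A, V, H)).astype(np.float32)
    smooth = gaussian_filter(noise, sigma=1.5)
    if spec.trabecular_fill <= 0.0:
        speckle = np.zeros_like(interior)
    elif spec.trabecular_fill >= 1.0:
        speckle = interior.copy()
    else:
        thr = np.quantile(smooth[interior], 1.0 - spec.trabecular_fill) \
            if interior.any() else np.inf
        speckle = interior & (smooth > thr)
    return shell_paint, shell_meas, interior, speckle


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Render one phantom volume; bit-reproducible for a fixed ``spec``."""
    spec.validate()
    shell, _, _, speckle = _geometry(spec)
    vol = np.zeros(shell.shape, dtype=np.float32)
    vol[speckle] = spec.trabecular_intensity
    vol[shell] = spec.cortical_intensity

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x9e1]))
    if spec.noise_sd > 0:
        vol = vol + rng.normal(scale=spec.noise_sd, size=vol.shape).astype(np.float32)
        vol = np.clip(vol, 0.0, 1.0)

    if spec.motion_artifact:
        # inter-slice motion: one contiguous axial block shifted in-plane
        A = spec.axial_slices
        lo = int(rng.integers(0, max(A - A // 4, 1)))
        hi = min(lo + max(A // 4, 1), A)
        vol[lo:hi] = np.roll(vol[lo:hi], spec.motion_severity, axis=2)
    return Volume(vol)


def generate_cohort(n: int, ranges: CohortRanges | None = None,
                    seed: int = 0, artifact_fraction: float = 0.17) -> list:
    """Draw ``n`` graded phantoms with extents uniform inside ``ranges``.

    A fraction ``artifact_fraction`` of volumes receives a motion artifact and
    a grade of 4 or 5.  Clean volumes get grades 1-3.  Grade correlates with
    image degradation (background noise for 1-3, shear severity for 4-5) so a
    grading classifier has actual signal to learn.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ranges = (ranges or CohortRanges()).validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xc0]))
    out = []
    for i in range(n):
        artifact = bool(rng.random() < artifact_fraction)
        if artifact:
            vgs = int(rng.integers(4, 6))
        else:
            vgs = int(rng.integers(1, 4))
        spec = PhantomSpec(
            axial_slices=ranges.axial_slices,
            vertical_extent=int(rng.integers(ranges.vertical[0], ranges.vertical[1] + 1)),
            horizontal_extent=int(rng.integers(ranges.horizontal[0], ranges.horizontal[1] + 1)),
            cortical_thickness=float(rng.uniform(*ranges.cortical_thickness)),
            cortical_intensity=float(rng.uniform(*ranges.cortical_intensity)),
            trabecular_fill=float(rng.uniform(*ranges.trabecular_fill)),
            noise_sd=0.02 + 0.04 * (vgs - 1),
            motion_artifact=artifact,
            motion_severity=4 * (vgs - 3) if artifact else 0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(GradedVolume(generate_phantom(spec), vgs))
    return out


def measure_density(v: Volume, compartment: str, geometry: PhantomSpec) -> float:
    """Mean grayscale over the named compartment of a phantom.

    ``geometry`` must be the spec that produced ``v`` (the compartment masks
    are regenerated from its seed).  This is the test-side analogue of the
    densitometric Ct.BMD / Tb.BMD read-outs on real scans.
    """
    _, shell_meas, interior, _ = _geometry(geometry.validate())
    if compartment == "cortical":
        mask = shell_meas
    elif compartment == "trabecular":
        mask = interior
    else:
        raise ValueError(f"unknown compartment: {compartment!r}")
    if v.shape != mask.shape:
        raise ValueError("volume shape does not match the phantom geometry")
    if not mask.any():
        return float("nan")
    return float(v.data[mask].mean())


def cohort_spec_grid(base: PhantomSpec, field: str, values) -> list:
    """Specs varying one field over ``values`` with everything else fixed."""
    return [replace(base, **{field: v}) for v in values]
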