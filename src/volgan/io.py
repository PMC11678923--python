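"""Volume and checkpoint I/O, dataset manifests, run configuration.

Axis convention at the file boundary: in-memory arrays are indexed
``(axial, vertical, horizontal)``; NIfTI/MetaImage store the reversed
(fastest-varying-first) order, so arrays are transposed on the way in and
out and spacing metadata is remapped accordingly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .volume import Volume

__all__ = ["read_volume", "write_volume", "VolumeFormatError",
           "Manifest", "ManifestRecord", "split_dataset",
           "load_config", "dump_config",
           "save_checkpoint", "load_checkpoint"]


class VolumeFormatError(ValueError):
    pass


def _nifti_suffix(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path) -> Volume:
    path = Path(path)
    name = path.name.lower()
    if _nifti_suffix(path):
        try:
            img = nib.load(str(path))
        except Exception as e:  # corrupt header
            raise VolumeFormatError(f"cannot read NIfTI {path}: {e}") from e
        data = np.asarray(img.dataobj).T     # (x,y,z) -> (axial, vert, horiz)
        zooms = img.header.get_zooms()[:3]
        spacing = tuple(float(z) for z in reversed(zooms))
        return Volume(data, spacing)
    if name.endswith(".mha") or name.endswith(".mhd"):
        try:
            img = sitk.ReadImage(str(path))
        except Exception as e:
            raise VolumeFormatError(f"cannot read MetaImage {path}: {e}") from e
        data = sitk.GetArrayFromImage(img)   # already (z, y, x)
        spacing = tuple(reversed(img.GetSpacing()))
        return Volume(data, spacing)
    if name.endswith(".npz"):
        with np.load(path) as f:
            return Volume(f["data"], tuple(f["spacing"]))
    raise VolumeFormatError(f"unsupported volume format: {path.suffix!r}")


def write_volume(v: Volume, path) -> None:
    path = Path(path)
    name = path.name.lower()
    if _nifti_suffix(path):
        affine = np.diag(list(reversed(v.spacing)) + [1.0])
        nib.save(nib.Nifti1Image(v.data.T.copy(), affine), str(path))
        return
    if name.endswith(".mha") or name.endswith(".mhd"):
        img = sitk.GetImageFromArray(v.data)
        img.SetSpacing(tuple(reversed(v.spacing)))
        sitk.WriteImage(img, str(path))
        return
    if name.endswith(".npz"):
        np.savez_compressed(path, data=v.data, spacing=np.asarray(v.spacing))
        return
    raise VolumeFormatError(f"unsupported volume format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# manifests and splits
# ---------------------------------------------------------------------------

@dataclass
class ManifestRecord:
    id: str
    path: str
    shape: tuple
    vgs: int | None = None
    split: str = "train"


@dataclass
class Manifest:
    records: list

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("manifest ids must be unique")

    def save(self, path) -> None:
        payload = [dataclasses.asdict(r) for r in self.records]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "Manifest":
        payload = json.loads(Path(path).read_text())
        return cls([ManifestRecord(**{**r, "shape": tuple(r["shape"])})
                    for r in payload])


def split_dataset(manifest: Manifest, fraction: float, seed: int) -> Manifest:
    """Assign a deterministic validation split of ``fraction`` of the records."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(manifest.records)
    perm = np.random.default_rng(seed).permutation(n)
    n_val = max(int(round(fraction * n)), 1)
    val = set(perm[:n_val].tolist())
    recs = [dataclasses.replace(r, split="val" if i in val else "train")
            for i, r in enumerate(manifest.records)]
    return Manifest(recs)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path, cls):
    """Load a YAML mapping into dataclass ``cls``; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in raw:
            val = raw[f.name]
            coerced[f.name] = tuple(val) if isinstance(val, list) else val
    return cls(**coerced)


def dump_config(cfg, path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in dataclasses.asdict(cfg).items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, groups: dict, meta: dict) -> None:
    """Single-file archive of named parameter groups plus JSON metadata.

    ``groups`` maps a group name (generator, critic, ...) to a state dict.
    """
    arrays = {}
    for gname, state in groups.items():
        for pname, arr in state.items():
            arrays[f"{gname}/{pname}"] = arr
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> tuple:
    groups: dict = {}
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        for key in f.files:
            if key == "__meta__":
                continue
            gname, pname = key.split("/", 1)
            groups.setdefault(gname, {})[pname] = f[key]
    return groups, meta
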