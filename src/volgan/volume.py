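"""The in-memory volume container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: HR-pQCT second-generation scanners acquire at ~61 micron isotropic voxels.
DEFAULT_SPACING_UM = (60.7, 60.7, 60.7)


@dataclass
class Volume:
    """A 3D grayscale image.

    ``data`` is indexed ``(axial, vertical, horizontal)``, 0-based.  ``spacing``
    is the voxel size in micrometres along the same axes; it is carried as
    metadata only and never enters any computation.
    """

    data: np.ndarray
    spacing: tuple = DEFAULT_SPACING_UM

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must have 3 axes, got {self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))

    @property
    def shape(self) -> tuple:
        return self.data.shape
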