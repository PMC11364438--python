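"""Two-channel 3-D brain stacks and voxel label masks.

Stacks are stored ``(channel, z, y, x)`` with channel 0 = nuclear stain and
channel 1 = F-actin stain.  On disk the interchange format is a multi-page
TIFF with channel-interleaved pages (page order: z0c0, z0c1, z1c0, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import tifffile

from .errors import InvalidInputError


class RegionLabel(IntEnum):
    """Voxel labels partitioning a brain volume."""

    BACKGROUND = 0
    CORTEX = 1
    NEUROPIL = 2
    EXCLUSION = 3


@dataclass
class BrainStack:
    """Two-channel 3-D intensity volume with isotropic-by-default voxels."""

    intensity: np.ndarray  # (2, nz, ny, nx), non-negative
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # um per (z, y, x)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 4 or self.intensity.shape[0] != 2:
            raise InvalidInputError(
                f"intensity must have shape (2, nz, ny, nx), got {self.intensity.shape}"
            )
        if np.any(self.intensity < 0):
            raise InvalidInputError("intensities must be non-negative")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size).ravel())
        if len(vs) == 1:
            vs = (vs[0],) * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise InvalidInputError("voxel_size must be 1 or 3 positive values (um)")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape[1:]

    @property
    def voxel_volume(self) -> float:
        vz, vy, vx = self.voxel_size
        return vz * vy * vx

    def to_tiff(self, path) -> None:
        """Write as multi-page TIFF, channel-interleaved pages."""
        nz = self.shape[0]
        pages = np.empty((nz * 2,) + self.intensity.shape[2:], dtype=np.float32)
        pages[0::2] = self.intensity[0]
        pages[1::2] = self.intensity[1]
        tifffile.imwrite(path, pages)

    @classmethod
    def from_tiff(cls, path, voxel_size=(1.0, 1.0, 1.0)) -> "BrainStack":
        pages = tifffile.imread(path)
        if pages.ndim != 3 or pages.shape[0] % 2 != 0:
            raise InvalidInputError(
                "expected a multi-page TIFF with an even number of "
                "channel-interleaved pages"
            )
        intensity = np.stack([pages[0::2], pages[1::2]], axis=0)
        return cls(intensity=np.maximum(intensity, 0.0), voxel_size=voxel_size)


@dataclass
class BrainMask:
    """Per-voxel labels: background / cortex / neuropil / exclusion."""

    labels: np.ndarray  # (nz, ny, nx) of RegionLabel values
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InvalidInputError("labels must be a 3-D array")
        valid = np.isin(self.labels, [int(l) for l in RegionLabel])
        if not valid.all():
            raise InvalidInputError("labels contain values outside the label set")

    @property
    def foreground(self) -> np.ndarray:
        """Cortex plus neuropil (lesion detection domain)."""
        return (self.labels == RegionLabel.CORTEX) | (self.labels == RegionLabel.NEUROPIL)

    @property
    def exclusion(self) -> np.ndarray:
        return self.labels == RegionLabel.EXCLUSION

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.labels.astype(np.uint8))

    @classmethod
    def from_tiff(cls, path, voxel_size=(1.0, 1.0, 1.0)) -> "BrainMask":
        return cls(labels=tifffile.imread(path), voxel_size=voxel_size)
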