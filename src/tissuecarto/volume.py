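"""Volumetric image containers.

Convention: image arrays are ordered ``(channel, z, y, x)`` and masks
``(z, y, x)``; ``spacing`` is the physical voxel size ``(dz, dy, dx)`` in μm.
Voxel ``(iz, iy, ix)`` is centred at the physical point
``(x, y, z) = (ix*dx, iy*dy, iz*dz)``, so meshes and volumes share one μm
frame with the origin at the centre of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VolumetricImage:
    """Multichannel intensity volume with physical voxel spacing."""

    data: np.ndarray  # (C, Z, Y, X)
    spacing: np.ndarray  # (dz, dy, dx) μm
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("data must be (channel, z, y, x)")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be > 0")
        if any(s < 2 for s in self.data.shape[1:]):
            raise ValueError("need at least 2 voxels per spatial axis")
        if not np.all(np.isfinite(self.data)):
            import warnings

            warnings.warn("volume contains non-finite values", stacklevel=2)
        if self.channel_names is not None and len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, index: int) -> np.ndarray:
        if not -self.n_channels <= index < self.n_channels:
            raise IndexError(f"channel {index} out of range (n={self.n_channels})")
        return self.data[index]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map physical ``(x, y, z)`` μm points to fractional ``(z, y, x)`` indices."""
        p = np.asarray(points, float)
        dz, dy, dx = self.spacing
        return np.stack([p[..., 2] / dz, p[..., 1] / dy, p[..., 0] / dx], axis=-1)

    def physical_extent(self) -> np.ndarray:
        """(x, y, z) extent in μm spanned by voxel centres."""
        nz, ny, nx = self.spatial_shape
        dz, dy, dx = self.spacing
        return np.array([(nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz])


@dataclass
class BinaryMask:
    """Boolean segmentation volume, ``(z, y, x)`` with the same μm frame."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be (z, y, x)")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be > 0")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_um3(self) -> float:
        return float(self.data.sum() * np.prod(self.spacing))
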