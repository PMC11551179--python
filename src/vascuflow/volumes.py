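"""Volumetric containers shared across the pipeline.

All volumes use the axis convention ``(z, x, y)`` with axis 0 pointing into
the tissue (increasing depth).  Physical coordinates are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    """Regular isotropic voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (z, x, y).
    voxel_size : float
        Isotropic voxel edge length in micrometres.
    origin : ndarray, shape (3,)
        Physical position (um) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid (um) along each axis."""
        return np.asarray(self.shape, dtype=float) * self.voxel_size

    def index_to_um(self, idx) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.voxel_size + np.asarray(self.origin)

    def um_to_index(self, pos) -> np.ndarray:
        """Continuous (fractional) voxel index of a physical position."""
        return (np.asarray(pos, dtype=float) - np.asarray(self.origin)) / self.voxel_size


@dataclass
class SegmentationMask:
    """Binary vessel mask on a voxel grid.

    ``provenance`` records whether the mask came from the internal
    thresholding baseline or an external segmentation (e.g. a released
    deep-learning model output that this package consumes).
    """

    data: np.ndarray
    grid: VoxelGrid
    provenance: str = "internal-threshold"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError("mask shape does not match grid")


@dataclass
class AngiogramVolume:
    """Non-negative flow-contrast volume (OCTA-style)."""

    data: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError("angiogram shape does not match grid")
        if np.any(self.data < 0):
            raise ValueError("angiogram values must be non-negative")
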