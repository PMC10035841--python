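"""Shared in-memory containers for the blastoderm spatial pipeline.

Conventions used throughout the package:

* 3D arrays are ordered ``(z, y, x)`` (ImageJ axis order); 2D images ``(y, x)``.
* Physical coordinates are micrometres measured from the stack/image origin
  (the corner of voxel ``(0, 0, 0)``); a voxel centre sits at
  ``(index + 0.5) * voxel_size``.
* The default lateral calibration is 0.5205 μm/px and the axial step 1.5 μm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: micrometres per pixel in x/y for all confocal-like imagery in this package.
UM_PER_PX: float = 0.5205

#: axial step between optical sections, micrometres.
Z_STEP_UM: float = 1.5


@dataclass
class VoxelStack:
    """A calibrated 3D intensity stack (one channel).

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Non-negative intensities, typically 12/16-bit range.
    voxel_size : tuple of float
        ``(dx, dy, dz)`` in micrometres.
    channel : str
        Label of the imaged channel (e.g. ``"nuclei"``, ``"ftz"``).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (UM_PER_PX, UM_PER_PX, Z_STEP_UM)
    channel: str = "nuclei"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"VoxelStack requires a 3D array, got ndim={self.values.ndim}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.values.size and self.values.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def index_to_um(self, zyx: np.ndarray) -> np.ndarray:
        """Convert fractional voxel indices ``(z, y, x)`` to ``(x, y, z)`` μm."""
        zyx = np.atleast_2d(np.asarray(zyx, dtype=float))
        dx, dy, dz = self.voxel_size
        out = np.column_stack([(zyx[:, 2] + 0.5) * dx, (zyx[:, 1] + 0.5) * dy, (zyx[:, 0] + 0.5) * dz])
        return out

    def um_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Convert ``(x, y, z)`` μm to fractional voxel indices ``(z, y, x)``."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        dx, dy, dz = self.voxel_size
        return np.column_stack([xyz[:, 2] / dz - 0.5, xyz[:, 1] / dy - 0.5, xyz[:, 0] / dx - 0.5])


@dataclass
class DensityRaster:
    """Gridded point-density surface in a registered frame.

    ``values[iy, ix]`` is the density (points per μm² by default) of the cell
    whose lower corner is ``origin + (ix, iy) * cell_size``; cells outside the
    mask polygon are NaN (undefined).
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    mask: object | None = None  # shapely geometry or None
    units: str = "per_um2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DensityRaster values must be 2D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return x, y

    def total_mass(self) -> float:
        """Integrated density (≈ number of points inside the mask)."""
        return float(np.nansum(self.values) * self.cell_size**2)


@dataclass
class NucleusTruth:
    """Ground-truth nucleus emitted by the synthetic generator."""

    id: int
    center: tuple[float, float, float]  # (x, y, z) μm
    radius: float  # μm
    markers: dict[str, bool] = field(default_factory=dict)


@dataclass
class MembraneTruth:
    """Ground-truth apical cell polygons for one synthetic membrane image."""

    polygons: list[np.ndarray]  # each (k, 2) array of (x, y) μm vertices
    areas: np.ndarray  # μm², shoelace areas of ``polygons``
    group: str = "dorsal"

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if len(self.polygons) != len(self.areas):
            raise ValueError("polygons and areas must have equal length")


def shoelace_area(vertices: np.ndarray) -> float:
    """Unsigned polygon area from its vertex chain (μm² if vertices in μm)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
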