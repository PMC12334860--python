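"""Voxel rasters and structure sets.

The universal raster is :class:`VoxelGrid`: a 3D scalar field (mass density in
g/cc, or absorbed dose in Gy, depending on context) with per-axis spacing and
a world-space origin.  Conventions, fixed package-wide:

* 0-based voxel indices, array axis order ``(x, y, z)``;
* world coordinates in mm; the world position of voxel ``(i, j, k)`` is the
  *center* of that voxel, ``origin + index * spacing``;
* structure masks are full-resolution binary rasters on the same geometry,
  defined by voxel-center-in-structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "StructureSet", "InvalidGeometryError"]


class InvalidGeometryError(ValueError):
    """Raised when a grid, mask or point violates the geometric contract."""


@dataclass
class VoxelGrid:
    """A 3D scalar field with spacing (mm) and origin (mm).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar per voxel (density in g/cc or dose in Gy by context).
    spacing : tuple of float
        Voxel size per axis in mm; all components must be positive.
    origin : tuple of float
        World position (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidGeometryError("values must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise InvalidGeometryError(f"spacing must be positive, got {self.spacing}")

    # -- geometry -----------------------------------------------------------
    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (= product of spacings / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def bounds_min(self) -> np.ndarray:
        """Lower corner (mm) of the voxelized box (outer voxel faces)."""
        return np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)

    @property
    def bounds_max(self) -> np.ndarray:
        return self.bounds_min + np.asarray(self.dims) * np.asarray(self.spacing)

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for (possibly fractional) indices."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, point: np.ndarray) -> np.ndarray:
        """Continuous voxel index of a world point (voxel centers at integers)."""
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_of(self, point: np.ndarray) -> tuple[int, int, int]:
        """Integer index of the voxel containing a world point."""
        idx = np.rint(self.world_to_index(point)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.dims)):
            raise InvalidGeometryError(f"point {point} outside grid")
        return tuple(int(i) for i in idx)

    def contains(self, point: np.ndarray) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.bounds_min) and np.all(p <= self.bounds_max))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid-free per-axis voxel center coordinates (mm)."""
        return tuple(
            self.origin[ax] + self.spacing[ax] * np.arange(self.dims[ax]) for ax in range(3)
        )

    def like(self, values: np.ndarray) -> "VoxelGrid":
        """A new grid with the same geometry and different values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.dims:
            raise InvalidGeometryError(
                f"values shape {values.shape} does not match grid dims {self.dims}"
            )
        return VoxelGrid(values, self.spacing, self.origin)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid geometry.

    ``BODY`` and ``PTV`` are required; the PTV must be non-empty and contained
    in the body.  Additional organ-at-risk masks are optional.
    """

    grid: VoxelGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        for label, mask in self.masks.items():
            if mask.shape != self.grid.dims:
                raise InvalidGeometryError(
                    f"mask {label!r} shape {mask.shape} != grid dims {self.grid.dims}"
                )
        for required in ("BODY", "PTV"):
            if required not in self.masks:
                raise InvalidGeometryError(f"structure set missing required label {required!r}")
        ptv, body = self.masks["PTV"], self.masks["BODY"]
        if not ptv.any():
            raise InvalidGeometryError("PTV mask is empty")
        if np.any(ptv & ~body):
            raise InvalidGeometryError("PTV extends outside BODY")

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.masks[label]
        except KeyError:
            raise KeyError(f"unknown structure label {label!r}; have {sorted(self.masks)}")

    def __contains__(self, label: str) -> bool:
        return label in self.masks

    @property
    def labels(self) -> list[str]:
        return sorted(self.masks)

    def volume_cc(self, label: str) -> float:
        """Structure volume in cc (voxel count × voxel volume)."""
        return float(self[label].sum()) * self.grid.voxel_volume_cc
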