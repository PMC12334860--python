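"""Synthetic planning phantoms.

Small CT-like density volumes with embedded spherical target and
organ-at-risk structures, emulating the planning problem (a deep-seated
sub-cc target near critical structures, with bone and lung heterogeneity)
so that every downstream stage is testable without clinical data.

Density surrogates (g/cc): water 1.0, cortical-bone shell 1.85, lung 0.26,
air 0.0 outside the body.
"""

from __future__ import annotations

import numpy as np

from .grid import InvalidGeometryError, StructureSet, VoxelGrid

__all__ = ["make_phantom", "hu_to_density", "PHANTOM_KINDS"]

WATER = 1.0
BONE = 1.85
LUNG = 0.26
AIR = 0.0

PHANTOM_KINDS = ("water_box", "cranial", "thorax", "abdomen")

# HU -> density (g/cc) piecewise-linear knots; clamped outside.
_HU_KNOTS = np.array([-1000.0, 0.0, 1000.0])
_RHO_KNOTS = np.array([0.001, 1.0, 1.6])


def hu_to_density(hu_grid: VoxelGrid) -> VoxelGrid:
    """Map a Hounsfield-unit grid to mass density (g/cc).

    Piecewise-linear with knots −1000 HU → 0.001, 0 HU → 1.0, 1000 HU → 1.6,
    clamped outside the knot range; monotone non-decreasing by construction.
    """
    rho = np.interp(hu_grid.values, _HU_KNOTS, _RHO_KNOTS)
    return hu_grid.like(rho)


def _sphere_mask(grid: VoxelGrid, center: np.ndarray, radius: float) -> np.ndarray:
    cx, cy, cz = grid.voxel_centers()
    d2 = (
        (cx - center[0])[:, None, None] ** 2
        + (cy - center[1])[None, :, None] ** 2
        + (cz - center[2])[None, None, :] ** 2
    )
    return d2 <= radius**2


def _ellipsoid_mask(grid: VoxelGrid, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    cx, cy, cz = grid.voxel_centers()
    d2 = (
        ((cx - center[0]) / semi[0])[:, None, None] ** 2
        + ((cy - center[1]) / semi[1])[None, :, None] ** 2
        + ((cz - center[2]) / semi[2])[None, None, :] ** 2
    )
    return d2 <= 1.0


def make_phantom(
    kind: str,
    dims: tuple[int, int, int] = (60, 60, 60),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    ptv_radius: float = 4.4,
    ptv_center: tuple[float, float, float] | None = None,
    seed: int = 0,
    oar_offset: tuple[float, float, float] | None = None,
    noise_sd: float | None = None,
) -> tuple[VoxelGrid, StructureSet]:
    """Build a synthetic density grid plus structure set.

    Parameters
    ----------
    kind : {"water_box", "cranial", "thorax", "abdomen"}
        water_box: homogeneous water body inset in air.
        cranial:   spherical head with a bone shell.
        thorax:    elliptical body with a lung block on one side.
        abdomen:   elliptical water body with mild density texture.
    dims, spacing
        Grid size (voxels) and voxel size (mm).
    ptv_radius : float
        Target sphere radius in mm; must exceed the largest voxel spacing.
    ptv_center : triple of float, optional
        World position (mm) of the target center; defaults to the grid center.
    seed : int
        Seeds the density texture of the heterogeneous phantoms; the geometry
        is deterministic regardless.
    oar_offset : triple of float, optional
        Offset (mm) from the PTV center to the organ-at-risk sphere center;
        defaults to ``(3 * ptv_radius, 0, 0)``.
    noise_sd : float, optional
        Standard deviation of the multiplicative soft-tissue density texture
        (heterogeneous kinds only); default 0.02.

    Returns
    -------
    (VoxelGrid, StructureSet)
        Density grid (g/cc) and masks with labels BODY, PTV, OAR.
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {PHANTOM_KINDS}")
    dims = tuple(int(d) for d in dims)
    spacing = tuple(float(s) for s in spacing)
    if ptv_radius <= max(spacing):
        raise InvalidGeometryError(
            f"ptv_radius {ptv_radius} mm must exceed the largest voxel spacing {max(spacing)} mm"
        )

    grid = VoxelGrid(np.zeros(dims), spacing=spacing, origin=(0.0, 0.0, 0.0))
    extent = np.asarray(dims) * np.asarray(spacing)
    center = grid.index_to_world((np.asarray(dims) - 1) / 2.0)
    ptv_center = np.asarray(ptv_center, dtype=float) if ptv_center is not None else center
    if not grid.contains(ptv_center):
        raise InvalidGeometryError(f"ptv_center {ptv_center} outside grid")

    rng = np.random.default_rng(seed)
    density = np.zeros(dims)

    if kind == "water_box":
        # body box inset by one voxel of air on every face
        body = np.zeros(dims, dtype=bool)
        body[1:-1, 1:-1, 1:-1] = True
        density[body] = WATER
    elif kind == "cranial":
        outer_r = 0.48 * float(extent.min())
        body = _sphere_mask(grid, center, outer_r)
        brain = _sphere_mask(grid, center, outer_r - 6.0)  # 6 mm skull shell
        density[body] = BONE
        density[brain] = WATER
    elif kind == "thorax":
        semi = 0.48 * extent
        body = _ellipsoid_mask(grid, center, semi)
        density[body] = WATER
        lung_center = center + np.array([0.4 * semi[0], 0.0, 0.0])
        lung = _ellipsoid_mask(grid, lung_center, 0.45 * semi) & body
        density[lung] = LUNG
    else:  # abdomen
        semi = 0.48 * extent
        body = _ellipsoid_mask(grid, center, semi)
        density[body] = WATER

    if kind != "water_box":
        sd = 0.02 if noise_sd is None else float(noise_sd)
        if sd > 0:
            soft = body & (density > 0.5 * WATER) & (density < 1.5 * WATER)
            density[soft] *= 1.0 + sd * rng.standard_normal(int(soft.sum()))
            np.clip(density, 0.0, None, out=density)

    ptv = _sphere_mask(grid, ptv_center, ptv_radius)
    if not ptv.any() or np.any(ptv & ~body):
        raise InvalidGeometryError("PTV is empty or extends outside BODY")

    if oar_offset is None:
        oar_offset = (3.0 * ptv_radius, 0.0, 0.0)
    oar = _sphere_mask(grid, ptv_center + np.asarray(oar_offset, dtype=float), ptv_radius) & body

    structures = StructureSet(grid=grid.like(density), masks={"BODY": body, "PTV": ptv, "OAR": oar})
    return grid.like(density), structures
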