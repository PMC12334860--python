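"""Non-coplanar plan setup: target sampling, approach regions, angle assignment.

The target volume is sampled with focal target points on a cubic lattice
spaced slightly wider than the lens's lateral FWHM (complete coverage with
minimal overlap).  For each point, the viable angular approach region is the
set of candidate directions (a deterministic Fibonacci lattice on the unit
sphere) whose water-equivalent depth to the point does not exceed the lens's
maximum penetration depth.  The region is then segmented into parts of equal
size by seeded spherical k-means, and each target point receives one
direction per segment, diversifying its approaches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid
from .lens import LensSpec
from .raytrace import NoSurfaceCrossingError, depth_to_point

__all__ = [
    "TargetPoint",
    "ApproachRegion",
    "UnreachableTargetError",
    "sample_target_points",
    "fibonacci_directions",
    "compute_approach_region",
    "assign_directions",
]


class UnreachableTargetError(ValueError):
    """A target point has no feasible approach direction."""


@dataclass(frozen=True)
class TargetPoint:
    """A candidate focal location inside the target volume."""

    id: int
    position: tuple[float, float, float]


@dataclass
class ApproachRegion:
    """Feasibility of candidate approach directions for one target point.

    ``depth[i]`` is the water-equivalent depth (mm) from the body surface to
    the point along ``candidate_directions[i]`` (NaN if the ray never enters
    the body); ``feasible[i]`` requires that depth to exist and not exceed
    the lens's maximum depth.
    """

    point_id: int
    candidate_directions: np.ndarray  # (n, 3) unit vectors
    feasible: np.ndarray  # (n,) bool
    depth: np.ndarray  # (n,) mm water-equivalent

    @property
    def feasible_directions(self) -> np.ndarray:
        return self.candidate_directions[self.feasible]

    @property
    def n_feasible(self) -> int:
        return int(self.feasible.sum())


def sample_target_points(
    ptv: np.ndarray, grid: VoxelGrid, lateral_fwhm: float, spacing_factor: float = 1.2
) -> list[TargetPoint]:
    """Lattice-sample focal target points inside the PTV.

    Points lie on a cubic lattice of pitch ``spacing_factor * lateral_fwhm``
    anchored at the PTV centroid, keeping nodes whose position falls in a PTV
    voxel.  If the lattice yields no point (target smaller than the pitch),
    the PTV centroid is returned as the single target point.
    """
    ptv = np.asarray(ptv, dtype=bool)
    if not ptv.any():
        raise ValueError("PTV mask is empty")
    if spacing_factor < 1:
        raise ValueError("spacing_factor must be >= 1")
    pitch = spacing_factor * lateral_fwhm

    vox = np.argwhere(ptv)
    centers = grid.index_to_world(vox)
    centroid = centers.mean(axis=0)

    lo, hi = centers.min(axis=0), centers.max(axis=0)
    offsets = []
    for ax in range(3):
        kmin = int(np.floor((lo[ax] - centroid[ax]) / pitch))
        kmax = int(np.ceil((hi[ax] - centroid[ax]) / pitch))
        offsets.append(np.arange(kmin, kmax + 1) * pitch)
    gx, gy, gz = np.meshgrid(*offsets, indexing="ij")
    nodes = centroid[None, :] + np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    inside = []
    for p in nodes:
        idx = np.rint(grid.world_to_index(p)).astype(int)
        if np.all(idx >= 0) and np.all(idx < np.asarray(grid.dims)) and ptv[tuple(idx)]:
            inside.append(p)

    if not inside:
        # degenerate lattice: fall back to the centroid (or nearest PTV voxel)
        idx = np.rint(grid.world_to_index(centroid)).astype(int)
        if np.all(idx >= 0) and np.all(idx < np.asarray(grid.dims)) and ptv[tuple(idx)]:
            inside = [centroid]
        else:
            nearest = vox[np.argmin(np.linalg.norm(centers - centroid, axis=1))]
            inside = [grid.index_to_world(nearest)]

    order = np.lexsort(tuple(np.asarray(inside).T[::-1]))
    return [
        TargetPoint(id=i, position=tuple(float(x) for x in np.asarray(inside)[j]))
        for i, j in enumerate(order)
    ]


def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors on the sphere (Fibonacci lattice)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def compute_approach_region(
    point: TargetPoint,
    density: VoxelGrid,
    body: np.ndarray,
    lens: LensSpec,
    n_candidates: int = 256,
) -> ApproachRegion:
    """Evaluate depth feasibility of candidate approach directions.

    A candidate direction is feasible iff a body-surface entry point exists
    along it and the water-equivalent depth from that entry to the target
    point does not exceed ``lens.max_depth``.
    """
    if n_candidates < 8:
        raise ValueError("n_candidates must be >= 8")
    dirs = fibonacci_directions(n_candidates)
    depths = np.full(n_candidates, np.nan)
    feasible = np.zeros(n_candidates, dtype=bool)
    for i, u in enumerate(dirs):
        try:
            d = depth_to_point(density, body, point.position, u)
        except NoSurfaceCrossingError:
            continue
        depths[i] = d
        feasible[i] = d <= lens.max_depth
    return ApproachRegion(point.id, dirs, feasible, depths)


def _seeded_kmeans_sphere(dirs: np.ndarray, k: int, seed: int, n_iter: int = 50) -> np.ndarray:
    """Plain k-means on unit vectors with the chordal metric; returns labels.

    Deterministic for a fixed seed; ties broken toward the lowest cluster
    index by argmin.
    """
    rng = np.random.default_rng(seed)
    centers = dirs[rng.choice(len(dirs), size=k, replace=False)]
    labels = np.zeros(len(dirs), dtype=int)
    for _ in range(n_iter):
        d2 = ((dirs[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            members = dirs[labels == j]
            if len(members):
                c = members.mean(axis=0)
                n = np.linalg.norm(c)
                centers[j] = c / n if n > 1e-12 else dirs[0]
    return labels


def assign_directions(
    region: ApproachRegion, n_segments: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Pick one representative direction per segment of the approach region.

    The feasible directions are partitioned into ``n_segments`` groups of
    near-equal size by seeded spherical k-means; the member closest to its
    group centroid represents each non-empty group (ties broken by lowest
    candidate index).  If ``n_segments`` meets or exceeds the feasible count,
    all feasible directions are returned.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    feas = region.feasible_directions
    if len(feas) == 0:
        raise UnreachableTargetError(
            f"target point {region.point_id} has no feasible approach direction"
        )
    if n_segments >= len(feas):
        return [f.copy() for f in feas]

    labels = _seeded_kmeans_sphere(feas, n_segments, seed)
    picks = []
    for j in range(n_segments):
        members = np.flatnonzero(labels == j)
        if members.size == 0:
            continue
        centroid = feas[members].mean(axis=0)
        n = np.linalg.norm(centroid)
        centroid = centroid / n if n > 1e-12 else feas[members[0]]
        d2 = ((feas[members] - centroid[None, :]) ** 2).sum(axis=1)
        picks.append(feas[members[np.argmin(d2)]].copy())
    return picks
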