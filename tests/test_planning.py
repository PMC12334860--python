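import numpy as np
import pytest

import clrt
from clrt.planning import UnreachableTargetError, fibonacci_directions


def sphere_ptv(grid_dims, spacing, radius, center=None):
    g = clrt.VoxelGrid(np.ones(grid_dims), spacing=spacing, origin=(0, 0, 0))
    center = np.asarray(center if center is not None else g.index_to_world(
        (np.array(grid_dims) - 1) / 2.0))
    cx, cy, cz = g.voxel_centers()
    d2 = ((cx - center[0])[:, None, None] ** 2 + (cy - center[1])[None, :, None] ** 2
          + (cz - center[2])[None, None, :] ** 2)
    return g, d2 <= radius**2, center


# -- target sampling ---------------------------------------------------------

def test_single_voxel_ptv_yields_its_center():
    g = clrt.VoxelGrid(np.ones((11, 11, 11)), spacing=(2, 2, 2), origin=(0, 0, 0))
    ptv = np.zeros((11, 11, 11), bool)
    ptv[4, 5, 6] = True
    pts = clrt.sample_target_points(ptv, g, lateral_fwhm=3.4, spacing_factor=1.2)
    assert len(pts) == 1
    np.testing.assert_allclose(pts[0].position, g.index_to_world([4, 5, 6]))


def test_lattice_count_matches_brute_force_enumeration():
    """Lattice nodes anchored at the centroid, pitch 4 mm, sphere radius 10 mm."""
    g, ptv, center = sphere_ptv((41, 41, 41), (1, 1, 1), 10.0)
    pts = clrt.sample_target_points(ptv, g, lateral_fwhm=4.0, spacing_factor=1.0)

    vox = np.argwhere(ptv)
    centroid = g.index_to_world(vox).mean(axis=0)
    count = 0
    for i in range(-4, 5):
        for j in range(-4, 5):
            for k in range(-4, 5):
                p = centroid + 4.0 * np.array([i, j, k])
                idx = np.rint(g.world_to_index(p)).astype(int)
                if np.all(idx >= 0) and np.all(idx < 41) and ptv[tuple(idx)]:
                    count += 1
    assert len(pts) == count
    for pt in pts:
        assert ptv[tuple(np.rint(g.world_to_index(pt.position)).astype(int))]


def test_pitch_larger_than_ptv_falls_back_to_centroid():
    g, ptv, center = sphere_ptv((31, 31, 31), (1, 1, 1), 3.0)
    pts = clrt.sample_target_points(ptv, g, lateral_fwhm=20.0, spacing_factor=1.2)
    assert len(pts) == 1
    np.testing.assert_allclose(pts[0].position, center, atol=1.0)


def test_empty_ptv_rejected():
    g = clrt.VoxelGrid(np.ones((5, 5, 5)))
    with pytest.raises(ValueError, match="empty"):
        clrt.sample_target_points(np.zeros((5, 5, 5), bool), g, 3.4)


def test_sampling_deterministic():
    g, ptv, _ = sphere_ptv((31, 31, 31), (1, 1, 1), 8.0)
    a = clrt.sample_target_points(ptv, g, 1.3, 1.2)
    b = clrt.sample_target_points(ptv, g, 1.3, 1.2)
    assert [p.position for p in a] == [p.position for p in b]


# -- approach regions --------------------------------------------------------

def test_fibonacci_directions_are_unit_and_spread():
    dirs = fibonacci_directions(128)
    np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
    assert np.linalg.norm(dirs.mean(axis=0)) < 0.05


def water_ball(radius_mm=40.0, spacing=2.0):
    n = int(2 * (radius_mm + 3 * spacing) / spacing) | 1
    g = clrt.VoxelGrid(np.zeros((n, n, n)), spacing=(spacing,) * 3, origin=(0, 0, 0))
    center = g.index_to_world([(n - 1) // 2] * 3)
    cx, cy, cz = g.voxel_centers()
    d2 = ((cx - center[0])[:, None, None] ** 2 + (cy - center[1])[None, :, None] ** 2
          + (cz - center[2])[None, None, :] ** 2)
    body = d2 <= radius_mm**2
    g.values[body] = 1.0
    return g, body, center


def test_center_of_40mm_ball_feasible_from_all_sides():
    g, body, center = water_ball(40.0)
    pt = clrt.TargetPoint(0, tuple(center))
    region = clrt.compute_approach_region(pt, g, body, clrt.builtin_lens("A"), 64)
    assert region.n_feasible == 64
    assert np.nanmax(region.depth) <= 46.0  # ~ball radius plus voxelization


def test_target_deeper_than_max_depth_everywhere_unreachable():
    """8 cm water-equivalent is the hard penetration limit: a 90 mm-deep
    target has an empty approach region."""
    g, body, center = water_ball(92.0, spacing=4.0)
    pt = clrt.TargetPoint(0, tuple(center))
    region = clrt.compute_approach_region(pt, g, body, clrt.builtin_lens("A"), 32)
    assert region.n_feasible == 0
    assert np.nanmin(region.depth) > 80.0
    with pytest.raises(UnreachableTargetError):
        clrt.assign_directions(region, 3, seed=0)


def test_shallow_point_under_slab_face_matches_per_direction_oracle():
    """10 mm under one face of a thick slab: feasibility must equal the
    brute-force depth check direction by direction."""
    dims = (50, 50, 56)
    g = clrt.VoxelGrid(np.zeros(dims), spacing=(4, 4, 4), origin=(0, 0, 0))
    body = np.zeros(dims, bool)
    body[1:-1, 1:-1, 1:-1] = True
    g.values[body] = 1.0
    point = (98.0, 98.0, 210.0)  # 10 mm under the upper-z face (z=220)
    lens = clrt.builtin_lens("A")
    pt = clrt.TargetPoint(0, point)
    region = clrt.compute_approach_region(pt, g, body, lens, 64)
    assert 0 < region.n_feasible < 64
    for u, feas in zip(region.candidate_directions, region.feasible):
        try:
            d = clrt.depth_to_point(g, body, point, u)
            assert feas == (d <= lens.max_depth)
        except Exception:
            assert not feas


def test_feasible_set_monotone_in_max_depth():
    g, body, center = water_ball(40.0)
    pt = clrt.TargetPoint(0, tuple(center + np.array([20.0, 0, 0])))
    feas = []
    for max_depth in (30.0, 50.0, 80.0):
        lens = clrt.LensSpec(fwhm_lateral=3.4, fwhm_longitudinal=22.5, max_depth=max_depth)
        region = clrt.compute_approach_region(pt, g, body, lens, 64)
        feas.append(region.feasible.copy())
    assert np.all(feas[0] <= feas[1])
    assert np.all(feas[1] <= feas[2])


# -- direction assignment ----------------------------------------------------

def hemisphere_region(n=128):
    dirs = fibonacci_directions(n)
    feasible = dirs[:, 2] > 0
    return clrt.ApproachRegion(0, dirs, feasible, np.where(feasible, 20.0, np.nan))


def test_single_segment_returns_one_feasible_direction():
    region = hemisphere_region()
    picks = clrt.assign_directions(region, 1, seed=0)
    assert len(picks) == 1
    assert any(np.allclose(picks[0], d) for d in region.feasible_directions)


def test_saturation_returns_all_feasible():
    dirs = fibonacci_directions(16)
    region = clrt.ApproachRegion(0, dirs, np.ones(16, bool), np.full(16, 10.0))
    picks = clrt.assign_directions(region, 20, seed=1)
    assert len(picks) == 16


def test_segment_sizes_near_equal_on_uniform_hemisphere():
    """k-means segmentation of a uniform hemisphere: group sizes within 20%
    of the mean group size."""
    from clrt.planning import _seeded_kmeans_sphere

    region = hemisphere_region(256)
    feas = region.feasible_directions
    labels = _seeded_kmeans_sphere(feas, 4, seed=0)
    sizes = np.bincount(labels, minlength=4)
    mean = sizes.mean()
    assert np.all(np.abs(sizes - mean) <= 0.2 * mean)


def test_assignment_deterministic_and_feasible():
    region = hemisphere_region()
    a = clrt.assign_directions(region, 4, seed=7)
    b = clrt.assign_directions(region, 4, seed=7)
    assert len(a) == 4
    np.testing.assert_array_equal(np.array(a), np.array(b))
    for u in a:
        assert any(np.allclose(u, d) for d in region.feasible_directions)
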