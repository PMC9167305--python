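"""Tests for point-cloud denoising, plane fitting and projection volume."""

import numpy as np
import pytest

from stereovol.fixtures import ShapeSpec, generate_shape_cloud
from stereovol.pointcloud_volume import (
    FilterParams,
    TriangulatedSurface,
    bilateral_filter,
    composite_volume,
    compute_volume,
    estimate_normals,
    fit_base_plane,
    triangulate_projection,
)
from stereovol.reconstruction import PointCloud


def _plane_cloud(n, extent=20.0, z=0.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(-extent / 2, extent / 2, size=(n, 2))
    zs = np.full(n, z) + (rng.normal(0, noise, n) if noise > 0 else 0.0)
    return PointCloud(points=np.column_stack([xy, zs]))


# ---------------------------------------------------------------------------
# normals


def test_normals_of_plane_are_vertical():
    cloud = _plane_cloud(400, z=5.0)
    normals, ok = estimate_normals(cloud, k=10)
    assert ok.all()
    np.testing.assert_allclose(np.abs(normals[:, 2]), 1.0, atol=1e-9)


def test_normals_of_sphere_are_radial():
    rng = np.random.default_rng(1)
    dirs = rng.normal(size=(3000, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    cloud = PointCloud(points=100.0 * dirs)
    normals, ok = estimate_normals(cloud, k=12)
    cosang = np.abs(np.einsum("ni,ni->n", normals, dirs))
    assert np.degrees(np.arccos(np.clip(cosang[ok], -1, 1))).max() < 5.0


def test_normals_require_enough_points():
    cloud = PointCloud(points=np.random.default_rng(0).random((5, 3)))
    with pytest.raises(ValueError):
        estimate_normals(cloud, k=10)


def test_normals_flag_collinear_neighborhoods():
    pts = np.column_stack([np.linspace(0, 10, 30), np.zeros(30), np.zeros(30)])
    _, ok = estimate_normals(PointCloud(points=pts), k=4)
    assert not ok.any()


# ---------------------------------------------------------------------------
# bilateral filter


def test_bilateral_coplanar_cloud_is_fixed_point():
    cloud = _plane_cloud(1500, z=3.0)
    out = bilateral_filter(cloud, FilterParams(k_neighbors=15))
    assert np.abs(out.points - cloud.points).max() < 1e-12


def test_bilateral_pulls_offset_point_toward_plane():
    base = _plane_cloud(2000, extent=10.0)
    pts = np.vstack([base.points, [0.0, 0.0, 0.4]])
    out = bilateral_filter(PointCloud(points=pts), FilterParams(k_neighbors=15))
    assert abs(out.points[-1, 2]) < 0.4


def test_bilateral_reduces_rms_of_noisy_plane():
    cloud = _plane_cloud(5000, noise=0.5, seed=0)
    rms_before = np.sqrt(np.mean(cloud.points[:, 2] ** 2))
    out = bilateral_filter(cloud, FilterParams(k_neighbors=15))
    rms_after = np.sqrt(np.mean(out.points[:, 2] ** 2))
    assert rms_after < rms_before


def test_bilateral_moves_points_only_along_normals():
    cloud = _plane_cloud(2000, noise=0.3, seed=2)
    normals, _ = estimate_normals(cloud, k=15)
    out = bilateral_filter(cloud, FilterParams(k_neighbors=15), normals=normals)
    delta = out.points - cloud.points
    lateral = delta - normals * np.einsum("ni,ni->n", delta, normals)[:, None]
    assert np.abs(lateral).max() < 1e-12


# ---------------------------------------------------------------------------
# base plane


def test_fit_base_plane_identity_for_flat_cloud():
    cloud, _ = generate_shape_cloud(
        ShapeSpec(kind="cuboid", width=8, depth=8, height=6), points_per_mm2=20, seed=0
    )
    frame = fit_base_plane(cloud)
    np.testing.assert_allclose(np.abs(frame.rotation[2]), [0, 0, 1], atol=1e-9)
    h = frame.to_frame(cloud.points)[:, 2]
    assert h.max() == pytest.approx(6.0, abs=1e-9)
    assert abs(h.min()) < 1e-9


def test_fit_base_plane_inverts_known_rotation():
    cloud, _ = generate_shape_cloud(
        ShapeSpec(kind="cuboid", width=8, depth=8, height=6), points_per_mm2=20, seed=0
    )
    angle = 0.4
    rot = np.array([
        [1, 0, 0],
        [0, np.cos(angle), -np.sin(angle)],
        [0, np.sin(angle), np.cos(angle)],
    ])
    moved = PointCloud(points=cloud.points @ rot.T + np.array([5.0, -3.0, 11.0]))
    h0 = fit_base_plane(cloud).to_frame(cloud.points)[:, 2]
    h1 = fit_base_plane(moved).to_frame(moved.points)[:, 2]
    np.testing.assert_allclose(h1, h0, atol=1e-6)


def test_fit_base_plane_uses_background_when_given():
    bg = _plane_cloud(500, z=0.0, seed=3)
    scene = PointCloud(points=np.vstack([bg.points, [[0, 0, 7.0]] * 5]))
    frame = fit_base_plane(scene, background=bg)
    h = frame.to_frame(scene.points)[:, 2]
    assert h[-1] == pytest.approx(7.0, abs=1e-9)


def test_fit_base_plane_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fit_base_plane(PointCloud(points=np.array([[0.0, 0, 0], [1, 0, 0]])))
    line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    with pytest.raises(ValueError):
        fit_base_plane(PointCloud(points=line))


# ---------------------------------------------------------------------------
# triangulation


def test_unit_square_splits_into_two_triangles():
    pts = np.array([[0, 0, 1.0], [1, 0, 1.0], [0, 1, 1.0], [1, 1, 1.0]])
    surf = triangulate_projection(pts)
    assert surf.n_triangles == 2


def test_delaunay_empty_circumcircle_property(rng):
    xy = rng.random((60, 2)) * 10
    pts = np.column_stack([xy, rng.random(60)])
    surf = triangulate_projection(pts)
    p = surf.points[:, :2]
    for tri in surf.triangles:
        a, b, c = p[tri]
        # circumcenter via perpendicular bisector intersection
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
        center = np.array([ux, uy])
        radius = np.linalg.norm(a - center)
        dist = np.linalg.norm(p - center, axis=1)
        assert (dist >= radius - 1e-9).all()


def test_duplicate_projections_keep_max_height():
    pts = np.array([
        [0, 0, 1.0], [1, 0, 2.0], [0, 1, 3.0],
        [1, 0, 7.0],  # duplicate (x, y) with larger height
    ])
    surf = triangulate_projection(pts)
    assert surf.n_duplicates == 1
    assert 7.0 in surf.points[:, 2]
    assert 2.0 not in surf.points[:, 2]


def test_collinear_projections_rejected():
    pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.ones(5)])
    with pytest.raises(ValueError):
        triangulate_projection(pts)


# ---------------------------------------------------------------------------
# composite volume


def test_prism_and_tetrahedron_patches():
    tri = np.array([[0, 0], [1, 0], [0, 1.0]])  # projected area 0.5
    surf = TriangulatedSurface(
        points=np.column_stack([tri, [1.0, 1.0, 1.0]]),
        triangles=np.array([[0, 1, 2]]),
    )
    assert composite_volume(surf) == pytest.approx(0.5)
    surf.points[:, 2] = [0.0, 0.0, 3.0]
    assert composite_volume(surf) == pytest.approx(0.5)  # (1/3) * base * height


def _decomposed_patch_volume(xy, h):
    """Patch solid via the prism + tetrahedra split into three tetrahedra."""
    bottom = np.column_stack([xy, np.zeros(3)])
    top = np.column_stack([xy, h])
    a0, b0, c0 = bottom
    a, b, c = top

    def tet(p0, p1, p2, p3):
        return abs(np.linalg.det(np.stack([p1 - p0, p2 - p0, p3 - p0]))) / 6.0

    return tet(a0, b0, c0, a) + tet(b0, c0, a, b) + tet(c0, a, b, c)


def test_mean_height_formula_equals_tetrahedral_decomposition(rng):
    for _ in range(1000):
        xy = rng.random((3, 2)) * 10
        h = rng.random(3) * 5
        e1, e2 = xy[1] - xy[0], xy[2] - xy[0]
        area = 0.5 * abs(e1[0] * e2[1] - e1[1] * e2[0])
        if area < 1e-6:
            continue
        v_mean = area * h.mean()
        v_dec = _decomposed_patch_volume(xy, h)
        assert v_mean == pytest.approx(v_dec, rel=1e-9)


def test_flat_slab_volume():
    g = np.linspace(0, 1, 50)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(2500, 2.0)])
    surf = triangulate_projection(pts)
    assert composite_volume(surf) == pytest.approx(2.0, rel=5e-3)


def test_composite_volume_non_negative(rng):
    pts = np.column_stack([rng.random((50, 2)) * 5, rng.normal(0, 1, 50)])
    surf = triangulate_projection(pts)
    assert composite_volume(surf) >= 0.0


# ---------------------------------------------------------------------------
# full volume pipeline


def test_cuboid_volume_within_one_percent():
    cloud, analytic = generate_shape_cloud(
        ShapeSpec(kind="cuboid", width=10, depth=10, height=10),
        points_per_mm2=200, seed=0,
    )
    report = compute_volume(cloud)
    assert report.volume_mm3 == pytest.approx(analytic, rel=0.01)
    assert report.n_triangles > 0


def test_noisy_cylinder_volume_within_five_percent():
    cloud, analytic = generate_shape_cloud(
        ShapeSpec(kind="cylinder", radius=6, height=20),
        points_per_mm2=100, noise_sigma=0.2, seed=0,
    )
    report = compute_volume(cloud)
    assert report.volume_mm3 == pytest.approx(analytic, rel=0.05)


def test_volume_invariant_under_rigid_motion():
    cloud, _ = generate_shape_cloud(
        ShapeSpec(kind="cuboid", width=10, depth=10, height=10),
        points_per_mm2=50, seed=1,
    )
    v0 = compute_volume(cloud).volume_mm3
    angle = 0.7
    rot = np.array([
        [np.cos(angle), -np.sin(angle), 0],
        [np.sin(angle), np.cos(angle), 0],
        [0, 0, 1.0],
    ])
    moved = PointCloud(points=cloud.points @ rot.T + np.array([40.0, -12.0, 3.0]))
    v1 = compute_volume(moved).volume_mm3
    assert v1 == pytest.approx(v0, rel=1e-6)


def test_volume_additivity_of_disjoint_shapes():
    c1, v1 = generate_shape_cloud(
        ShapeSpec(kind="cuboid", width=8, depth=8, height=10), points_per_mm2=100, seed=0
    )
    c2, v2 = generate_shape_cloud(
        ShapeSpec(kind="cylinder", radius=5, height=12), points_per_mm2=100, seed=1
    )
    shift = np.array([40.0, 0.0, 0.0])
    both = PointCloud(points=np.vstack([c1.points, c2.points + shift]))
    va = compute_volume(c1).volume_mm3
    vb = compute_volume(PointCloud(points=c2.points + shift)).volume_mm3
    vab = compute_volume(both).volume_mm3
    assert vab == pytest.approx(va + vb, rel=0.01)


def test_empty_after_subtraction_gives_zero_volume(rng):
    pts = rng.uniform(0, 10, size=(100, 3))
    cloud = PointCloud(points=pts)
    report = compute_volume(cloud, background=cloud, eps=1.0)
    assert report.volume_mm3 == 0.0
    assert report.n_points_after_subtract == 0


def test_filter_params_validation():
    with pytest.raises(ValueError):
        FilterParams(k_neighbors=2)
    with pytest.raises(ValueError):
        FilterParams(sigma_c=-1.0)
    with pytest.raises(ValueError):
        FilterParams(iterations=0)
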