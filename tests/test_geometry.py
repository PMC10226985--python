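"""Geometric morphometrics against analytic and brute-force oracles."""

import numpy as np
import pytest
import trimesh
from scipy.optimize import brentq

from conftest import digital_ball, sphere_cloud

from embryoquant import (
    OrientedBox,
    SurfacePointCloud,
    apical_surface_area,
    aspect_ratio,
    distance_to_embryo_cm,
    extract_apical_surface,
    fit_ellipsoid,
    flatness,
    local_mean_curvature,
    mask_to_mesh,
    nuclear_deformation_index,
    oriented_bounding_box,
    sphericity,
    surface_points_from_mask,
    wrinkled_sphere_cloud,
)
from embryoquant.geometry import _inplane_extents, _orthonormal_frame


class TestSurfacePoints:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        pc = surface_points_from_mask(mask, (2.0, 0.5, 0.5))
        np.testing.assert_allclose(pc.points, [[3.0, 0.75, 0.75]])

    def test_ball_boundary_at_radius(self):
        spacing = (0.5, 0.5, 0.5)
        mask = digital_ball(10.0, spacing)
        pc = surface_points_from_mask(mask, spacing)
        r = np.linalg.norm(pc.points - 12.0, axis=1)
        diag = np.linalg.norm(spacing)
        assert np.all((r >= 10 - diag) & (r <= 10 + diag))

    def test_volume_filling_mask_rejected(self):
        with pytest.raises(ValueError, match="no background"):
            surface_points_from_mask(np.ones((4, 4, 4), bool), (1, 1, 1))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            surface_points_from_mask(np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestApicalSurface:
    def test_contact_cap_faces_away(self):
        a = SurfacePointCloud(sphere_cloud(10.0, 4000, center=(0, 0, 0)))
        b = SurfacePointCloud(sphere_cloud(10.0, 4000, center=(20, 0, 0), seed=1))
        apical = extract_apical_surface(a, [b], cutoff_um=2.0)
        assert 0 < len(apical) < len(a)
        # retained points face away from the contact (+z side towards b)
        assert apical.points[:, 0].mean() < 0

    def test_no_neighbors_keeps_full_surface(self):
        a = SurfacePointCloud(sphere_cloud(5.0, 500))
        apical = extract_apical_surface(a, [], cutoff_um=1.0)
        assert len(apical) == len(a)

    def test_fully_surrounded_cell_empty(self):
        a = SurfacePointCloud(sphere_cloud(5.0, 500))
        shell = SurfacePointCloud(sphere_cloud(5.3, 4000, seed=2))
        apical = extract_apical_surface(a, [shell], cutoff_um=1.0)
        assert len(apical) == 0

    def test_points_at_exact_cutoff_retained(self):
        a = SurfacePointCloud(np.array([[0.0, 0, 0], [0.0, 0, 5]]))
        nb = SurfacePointCloud(np.array([[0.0, 0, 6]]))
        apical = extract_apical_surface(a, [nb], cutoff_um=1.0)
        assert len(apical) == 2  # distance exactly 1.0 is kept


class TestApicalArea:
    def test_spherical_cap_area_analytic(self):
        R, h = 10.0, 3.0
        pts = sphere_cloud(R, 40000)
        full = SurfacePointCloud(pts)
        cap = SurfacePointCloud(pts[pts[:, 0] >= R - h], source="apical_subset")
        area = apical_surface_area(cap, cell=full)
        assert area == pytest.approx(2 * np.pi * R * h, rel=0.05)

    def test_right_triangle(self):
        tri = SurfacePointCloud(np.array([[0.0, 0, 0], [0.0, 3, 0], [0.0, 0, 4]]))
        assert apical_surface_area(tri) == pytest.approx(6.0)

    def test_empty_set_zero(self):
        assert apical_surface_area(SurfacePointCloud(np.empty((0, 3)))) == 0.0

    def test_partition_sanity_on_sphere(self):
        """Apical + non-apical hull facets recover ≈ the full hull area."""
        pts = sphere_cloud(8.0, 6000)
        full = SurfacePointCloud(pts)
        upper = SurfacePointCloud(pts[pts[:, 0] >= 0], source="apical_subset")
        lower = SurfacePointCloud(pts[pts[:, 0] < 0], source="apical_subset")
        total = apical_surface_area(full)
        a = apical_surface_area(upper, cell=full)
        b = apical_surface_area(lower, cell=full)
        assert a + b >= 0.95 * total


class TestOrientedBox:
    def test_axis_aligned_box_extents(self):
        rng = np.random.default_rng(0)
        zs = rng.uniform(0, 20, 4000)
        ys = rng.uniform(0, 10, 4000)
        xs = rng.uniform(0, 10, 4000)
        # include the corners so extents are exact
        pts = np.column_stack([zs, ys, xs])
        corners = np.array([[z, y, x] for z in (0, 20.0) for y in (0, 10.0) for x in (0, 10.0)])
        cloud = SurfacePointCloud(np.vstack([pts, corners]))
        apical = SurfacePointCloud(corners[corners[:, 0] == 20.0], source="apical_subset")
        box = oriented_bounding_box(cloud, np.array([-30.0, 5.0, 5.0]), apical)
        assert box.Lz == pytest.approx(20.0, rel=0.01)
        assert sorted([box.Lx, box.Ly]) == pytest.approx([10.0, 10.0], rel=0.02)

    def test_sphere_extents_equal_diameter(self):
        cloud = SurfacePointCloud(sphere_cloud(7.0, 8000))
        box = oriented_bounding_box(cloud, np.array([-30.0, 0, 0]), None)
        for L in (box.Lx, box.Ly, box.Lz):
            assert L == pytest.approx(14.0, rel=0.02)
        assert box.radial_fallback

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_rotation_search(self, seed):
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        pts = rng.normal(size=(200, 3)) @ np.diag(rng.uniform(2, 9, 3)) @ q
        cloud = SurfacePointCloud(pts)
        cm = np.array([0.0, 0.0, -40.0])
        box = oriented_bounding_box(cloud, cm, None)
        frame = _orthonormal_frame(cloud.centroid - cm)
        xy = ((pts - cm) @ frame.T)[:, :2]
        best = min(
            np.prod(_inplane_extents(xy, a)) for a in np.deg2rad(np.arange(0, 90, 0.05))
        )
        assert box.Lx * box.Ly <= best * 1.01

    def test_zero_radial_vector_rejected(self):
        cloud = SurfacePointCloud(sphere_cloud(5.0, 100))
        with pytest.raises(ValueError):
            oriented_bounding_box(cloud, cloud.centroid, None)


class TestShapeDescriptors:
    @pytest.mark.parametrize(
        "Lz,Lx,Ly,expected",
        [(20, 10, 10, 1 / 3), (10, 10, 10, 0.0), (5, 10, 8, -1 / 3)],
    )
    def test_aspect_ratio_formula(self, Lz, Lx, Ly, expected):
        box = OrientedBox(Lx=Lx, Ly=Ly, Lz=Lz, Lz_api=0.0, frame=np.eye(3))
        assert aspect_ratio(box) == pytest.approx(expected)

    def test_flatness_limits(self):
        flat = OrientedBox(Lx=5, Ly=5, Lz=10, Lz_api=0.01, frame=np.eye(3))
        assert flatness(flat) == pytest.approx(0.001)
        full = OrientedBox(Lx=5, Ly=5, Lz=10, Lz_api=10.0, frame=np.eye(3))
        assert flatness(full) == 1.0

    def test_flatness_hemispherical_cap(self):
        pts = sphere_cloud(10.0, 20000)
        full = SurfacePointCloud(pts)
        cap = SurfacePointCloud(pts[pts[:, 0] >= 0], source="apical_subset")
        box = oriented_bounding_box(full, np.array([-30.0, 0, 0]), cap)
        assert flatness(box) == pytest.approx(0.5, abs=0.02)

    def test_distance_to_cm(self):
        assert distance_to_embryo_cm([1, 2, 3], [1, 2, 3]) == 0.0
        assert distance_to_embryo_cm([3, 4, 0], [0, 0, 0]) == 5.0


class TestEllipsoidFit:
    def test_sphere_semi_axes(self):
        fit = fit_ellipsoid(SurfacePointCloud(sphere_cloud(8.0, 500, center=(3, -2, 7))))
        np.testing.assert_allclose(fit.semi_axes, [8, 8, 8], rtol=0.01)
        np.testing.assert_allclose(fit.center, [3, -2, 7], atol=0.05)

    def test_exact_ellipsoid_recovered(self):
        rng = np.random.default_rng(1)
        th = np.arccos(rng.uniform(-1, 1, 600))
        phi = rng.uniform(0, 2 * np.pi, 600)
        pts = np.stack(
            [10 * np.cos(th), 7 * np.sin(th) * np.sin(phi), 5 * np.sin(th) * np.cos(phi)], 1
        )
        fit = fit_ellipsoid(SurfacePointCloud(pts + np.array([1.0, 2.0, 3.0])))
        np.testing.assert_allclose(fit.semi_axes, [10, 7, 5], rtol=0.01)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="9 points"):
            fit_ellipsoid(SurfacePointCloud(sphere_cloud(5.0, 5)))

    def test_rigid_motion_invariance(self):
        pts = wrinkled_sphere_cloud(8.0, 0.1, order=4, n_points=600, seed=0)
        idx0 = nuclear_deformation_index(SurfacePointCloud(pts))
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + np.array([11.0, -4.0, 2.0])
        idx1 = nuclear_deformation_index(SurfacePointCloud(moved))
        assert idx1 == pytest.approx(idx0, rel=1e-6)

    def test_scale_invariance_of_index(self):
        pts = wrinkled_sphere_cloud(8.0, 0.1, order=4, n_points=600, seed=0)
        idx0 = nuclear_deformation_index(SurfacePointCloud(pts))
        idx1 = nuclear_deformation_index(SurfacePointCloud(pts * 3.0))
        assert idx1 == pytest.approx(idx0, rel=1e-9)


class TestDeformationIndex:
    def test_zero_on_exact_ellipsoid(self):
        rng = np.random.default_rng(1)
        th = np.arccos(rng.uniform(-1, 1, 500))
        phi = rng.uniform(0, 2 * np.pi, 500)
        pts = np.stack(
            [9 * np.cos(th), 6 * np.sin(th) * np.sin(phi), 5 * np.sin(th) * np.cos(phi)], 1
        )
        cloud = SurfacePointCloud(pts)
        assert nuclear_deformation_index(cloud) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("amplitude", [0.05, 0.1, 0.2])
    def test_matches_brute_force_radial_oracle(self, amplitude):
        pts = wrinkled_sphere_cloud(8.0, amplitude, order=4, n_points=600, seed=2)
        cloud = SurfacePointCloud(pts)
        fit = fit_ellipsoid(cloud)
        # oracle: root-find the ray-ellipsoid intersection per point
        total = 0.0
        for p in pts:
            d = p - fit.center
            f = lambda s: float(np.sum(((fit.orientation @ (s * d)) / fit.semi_axes) ** 2) - 1.0)
            s = brentq(f, 1e-9, 10.0)
            total += abs(np.linalg.norm(d) - np.linalg.norm(s * d)) / np.linalg.norm(d)
        oracle = total / len(pts)
        assert nuclear_deformation_index(cloud, fit) == pytest.approx(oracle, rel=0.02)

    def test_cosine_perturbation_matches_numeric_integration(self):
        """r = R(1 + a cos kθ): index approaches a · <|cos kθ|> for small a."""
        R, a, k = 10.0, 0.1, 6
        rng = np.random.default_rng(3)
        v = rng.normal(size=(4000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        theta = np.arccos(np.clip(v[:, 0], -1, 1))
        pts = v * (R * (1 + a * np.cos(k * theta)))[:, None]
        idx = nuclear_deformation_index(SurfacePointCloud(pts))
        th = np.linspace(0, np.pi, 20001)
        pert = a * np.cos(k * th)
        expected = np.trapezoid(np.abs(pert) / (1 + pert) * np.sin(th), th) / 2.0
        assert idx == pytest.approx(expected, rel=0.05)


class TestSphericityAndCurvature:
    def test_digital_ball_near_one(self):
        spacing = (0.5, 0.25, 0.25)
        assert sphericity(digital_ball(10.0, spacing), spacing) >= 0.97

    def test_ellipsoid_matches_thomsen_area(self):
        spacing = (0.5, 0.25, 0.25)
        extent = 12.0
        shape = [int(np.ceil(2 * extent / s)) for s in spacing]
        axes = [(np.arange(n) + 0.5) * s - extent for n, s in zip(shape, spacing)]
        Z, Y, X = np.meshgrid(*axes, indexing="ij")
        ell = (Z / 10) ** 2 + (Y / 5) ** 2 + (X / 5) ** 2 <= 1
        p = 1.6075
        a, b, c = 10.0, 5.0, 5.0
        area = 4 * np.pi * ((a**p * b**p + a**p * c**p + b**p * c**p) / 3) ** (1 / p)
        volume = 4 / 3 * np.pi * a * b * c
        psi = np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area
        assert sphericity(ell, spacing) == pytest.approx(psi, rel=0.03)

    def test_wrinkled_nucleus_less_spherical(self):
        from embryoquant import PhantomSpec, generate_embryo_phantom

        base = dict(
            n_cells=1, embryo_radius=14, cell_radius_mean=12,
            noise_gaussian_sd=0, noise_poisson_scale=0,
            voxel_spacing=(0.5, 0.25, 0.25),
        )
        smooth = generate_embryo_phantom(PhantomSpec(**base))
        wrinkled = generate_embryo_phantom(PhantomSpec(wrinkle_amplitude=0.15, **base))
        s0 = sphericity(smooth.truth_nuclei.labels == 1, (0.5, 0.25, 0.25))
        s1 = sphericity(wrinkled.truth_nuclei.labels == 1, (0.5, 0.25, 0.25))
        assert s1 < s0

    def test_sphere_mesh_curvature_one_over_r(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=8.0)
        H = local_mean_curvature(mesh)
        assert np.mean(np.abs(H - 1 / 8) <= 0.1 / 8) > 0.95

    def test_plane_like_patch_near_zero(self):
        # giant sphere: locally flat; curvature two orders below 1/µm scales
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=1000.0)
        H = local_mean_curvature(mesh)
        assert np.all(np.abs(H) < 0.01)

    def test_irregular_shape_higher_curvature_sd(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=8.0)
        spacing = (0.5, 0.5, 0.5)
        from embryoquant import PhantomSpec, generate_embryo_phantom

        ph = generate_embryo_phantom(
            PhantomSpec(
                n_cells=1, embryo_radius=14, cell_radius_mean=12,
                wrinkle_amplitude=0.15, noise_gaussian_sd=0, noise_poisson_scale=0,
                voxel_spacing=spacing,
            )
        )
        wrinkly = mask_to_mesh(ph.truth_nuclei.labels == 1, spacing)
        assert np.std(local_mean_curvature(wrinkly)) > np.std(local_mean_curvature(sphere))

    def test_open_mesh_rejected_unless_allowed(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        open_mesh = trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.faces[:-10], process=False
        )
        with pytest.raises(ValueError):
            local_mean_curvature(open_mesh)
        assert len(local_mean_curvature(open_mesh, allow_boundary=True)) == len(mesh.vertices)
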