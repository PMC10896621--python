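"""Simulated acquisition chain: rendering, discretisation, smoothing,
back-projection, calibration, merging and surface reconstruction."""

import math

import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree

from ruminant3d import capture as cap


def make_cam(**kw):
    defaults = dict(fx=300.0, fy=300.0, cx=160.0, cy=120.0, width=320, height=240)
    defaults.update(kw)
    return cap.CameraModel(**defaults)


@pytest.fixture()
def frontal_plane():
    """Large plane orthogonal to the optical axis at z = 2 m."""
    return trimesh.Trimesh(
        vertices=[[-5, -5, 2], [5, -5, 2], [5, 5, 2], [-5, 5, 2]],
        faces=[[0, 1, 2], [0, 2, 3]],
    )


class TestRender:
    def test_frontal_plane_exact_depth(self, frontal_plane):
        d = cap.render_depth(frontal_plane, make_cam())
        assert d.valid.all()
        assert np.abs(d.depth - 2.0).max() < 1e-9

    def test_sphere_center_pixel_depth(self):
        # unit sphere at distance 3 with a mesh vertex at the near pole
        sph = trimesh.creation.uv_sphere(radius=1.0, count=[96, 96])
        sph.apply_translation([0, 0, 3])
        d = cap.render_depth(sph, make_cam())
        assert d.depth[120, 160] == pytest.approx(2.0, abs=1e-6)

    def test_camera_inside_mesh_invalid(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        with pytest.warns(UserWarning, match="inside"):
            d = cap.render_depth(sph, make_cam())
        assert not d.valid.any()

    def test_rendered_points_on_surface(self, adult_mesh):
        cam = cap.default_rig(width=320, height=180).cameras[7]
        d = cap.render_depth(adult_mesh, cam)
        d = cap.quantize_depth(d, 0.002)
        pc = cap.backproject(d, cam)
        samples = np.vstack([adult_mesh.vertices, adult_mesh.triangles_center])
        dist, _ = cKDTree(samples).query(pc.points, workers=-1)
        # within quantization step + mesh sampling density
        assert np.percentile(dist, 99) < 0.002 + 0.01


class TestQuantize:
    def test_zero_step_identity(self, frontal_plane):
        d = cap.render_depth(frontal_plane, make_cam())
        q = cap.quantize_depth(d, 0.0)
        assert np.array_equal(q.depth, d.depth)

    def test_rounding(self):
        d = cap.DepthMap(np.array([[1.004, 1.006]]), np.ones((1, 2), bool))
        q = cap.quantize_depth(d, 0.01)
        assert np.allclose(q.depth, [[1.00, 1.01]])

    def test_rms_error_uniform_law(self):
        rng = np.random.default_rng(0)
        d = cap.DepthMap(rng.uniform(1, 2, (500, 500)), np.ones((500, 500), bool))
        q = cap.quantize_depth(d, 0.01)
        rms = float(np.sqrt(np.mean((q.depth - d.depth) ** 2)))
        assert rms == pytest.approx(0.01 / math.sqrt(12.0), rel=0.02)


class TestSmooth:
    def test_constant_map_unchanged(self):
        d = cap.DepthMap(np.full((40, 40), 2.0), np.ones((40, 40), bool))
        s = cap.smooth_depth(d, 3, 0.002)
        assert np.abs(s.depth - 2.0).max() < 1e-12

    def test_staircase_variance_reduction(self):
        vv, uu = np.mgrid[0:120, 0:160]
        true = 1.5 + 0.0004 * uu + 0.0007 * vv  # tilted plane
        q = cap.quantize_depth(cap.DepthMap(true.copy(), np.ones_like(true, bool)), 0.002)
        s = cap.smooth_depth(q, spatial_radius=3, range_sigma=0.006)
        inner = (slice(5, -5), slice(5, -5))
        rms_q = np.sqrt(np.mean((q.depth[inner] - true[inner]) ** 2))
        rms_s = np.sqrt(np.mean((s.depth[inner] - true[inner]) ** 2))
        assert rms_q / rms_s >= 3.0

    def test_depth_edge_preserved(self):
        vv, uu = np.mgrid[0:60, 0:120]
        step = np.where(uu < 60, 1.5, 1.6)  # 0.1 m jump >> 5 * range_sigma
        d = cap.DepthMap(step.astype(float), np.ones_like(step, bool))
        s = cap.smooth_depth(d, spatial_radius=3, range_sigma=0.002)
        assert np.abs(s.depth - step).max() < 1e-3

    def test_mask_unchanged(self):
        rng = np.random.default_rng(1)
        valid = rng.random((50, 50)) > 0.3
        d = cap.DepthMap(np.where(valid, 2.0, 0.0), valid)
        s = cap.smooth_depth(d, 2, 0.004)
        assert np.array_equal(s.valid, valid)


class TestBackproject:
    def test_principal_point_on_axis(self, frontal_plane):
        cam = make_cam()
        pc = cap.backproject(cap.render_depth(frontal_plane, cam), cam)
        # the pixel at the principal point maps onto the optical axis
        idx = np.argmin(np.linalg.norm(pc.points[:, :2], axis=1))
        assert pc.points[idx] == pytest.approx([0.0, 0.0, 2.0], abs=1e-2)

    def test_plane_normal_within_degree(self):
        # tilted plane: fitted normals agree with the analytic normal
        v = np.array([[-5, -5, 2.0], [5, -5, 2.5], [5, 5, 3.0], [-5, 5, 2.5]])
        plane = trimesh.Trimesh(vertices=v, faces=[[0, 1, 2], [0, 2, 3]])
        cam = make_cam()
        pc = cap.backproject(cap.render_depth(plane, cam), cam)
        n_true = np.cross(v[1] - v[0], v[3] - v[0])
        n_true = n_true / np.linalg.norm(n_true)
        mean_n = pc.normals.mean(axis=0)
        mean_n /= np.linalg.norm(mean_n)
        angle = math.degrees(math.acos(abs(float(np.dot(mean_n, n_true)))))
        assert angle < 1.0

    def test_normals_camera_facing(self, adult_mesh):
        cam = cap.default_rig(width=320, height=180).cameras[2]
        pc = cap.backproject(cap.render_depth(adult_mesh, cam), cam)
        to_cam = cam.position - pc.points
        dots = np.einsum("ij,ij->i", pc.normals, to_cam)
        assert (dots > 0).mean() > 0.99

    def test_pose_roundtrip(self):
        rng = np.random.default_rng(3)
        R = trimesh.transformations.rotation_matrix(0.7, [0.1, 0.9, 0.3])[:3, :3]
        pose = cap.Pose(R, np.array([0.4, -1.2, 2.0]))
        pts = rng.normal(size=(50, 3))
        assert np.abs(pose.inverse().apply(pose.apply(pts)) - pts).max() < 1e-9


class TestCalibration:
    def test_identity(self):
        pts = np.random.default_rng(0).uniform(-0.5, 0.5, (12, 3))
        pose = cap.calibrate_pair(pts, pts)
        assert np.abs(pose.rotation - np.eye(3)).max() < 1e-12
        assert np.abs(pose.translation).max() < 1e-12

    def test_known_transform_recovered(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(-0.5, 0.5, (40, 3))
        R = trimesh.transformations.rotation_matrix(math.radians(30), [0, 0, 1])[:3, :3]
        t = np.array([0.5, 0.0, 0.0])
        pose = cap.calibrate_pair(A, A @ R.T + t)
        assert np.abs(pose.rotation - R).max() < 1e-6
        assert np.abs(pose.translation - t).max() < 1e-6

    def test_collinear_corners_rejected(self):
        line = np.outer(np.linspace(0, 1, 10), [1.0, 2.0, 0.5])
        with pytest.raises(cap.CalibrationError, match="collinear"):
            cap.calibrate_pair(line, line)

    def test_noise_robustness(self):
        """1 mm corner noise on 40 corners: translation error below
        2 mm for 95% of trials."""
        rng = np.random.default_rng(5)
        R = trimesh.transformations.rotation_matrix(0.4, [0.2, 1.0, 0.1])[:3, :3]
        t = np.array([0.3, -0.2, 0.8])
        errs = []
        for _ in range(100):
            A = rng.uniform(-0.4, 0.4, (40, 3))
            B = A @ R.T + t + rng.normal(0, 0.001, (40, 3))
            pose = cap.calibrate_pair(A, B)
            errs.append(np.linalg.norm(pose.translation - t))
        assert np.percentile(errs, 95) < 0.002

    def test_pairwise_chain_closes(self):
        """Composing noise-free pairwise calibrations around the rig
        returns to the start within accumulated tolerance."""
        rig = cap.default_rig(width=64, height=48)
        rng = np.random.default_rng(9)
        board_world = rng.uniform(-0.5, 0.5, (30, 3)) + [0, 0, 1.0]
        chain = cap.Pose.identity()
        cams = rig.cameras
        for a, b in zip(cams, cams[1:] + cams[:1]):
            pa = a.pose.inverse().apply(board_world)
            pb = b.pose.inverse().apply(board_world)
            chain = cap.calibrate_pair(pa, pb).compose(chain)
        assert np.abs(chain.rotation - np.eye(3)).max() < 15 * 1e-6
        assert np.abs(chain.translation).max() < 15 * 1e-6


class TestMerge:
    def test_single_cloud_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(100, 3))
        nrm = np.tile([0.0, 0.0, 1.0], (100, 1))
        c = cap.OrientedPointCloud(pts, nrm, np.zeros(100))
        merged = cap.merge_clouds([c], [cap.Pose.identity()], dedup_radius=0.0)
        assert np.array_equal(merged.points, pts)

    def test_pose_count_mismatch(self):
        c = cap.OrientedPointCloud(np.zeros((5, 3)), np.ones((5, 3)), np.zeros(5))
        with pytest.raises(ValueError, match="poses"):
            cap.merge_clouds([c, c], [cap.Pose.identity()])

    def test_two_half_sphere_scans(self):
        """Opposite-camera scans of a sphere merge onto the analytic
        surface within the quantization step."""
        sph = trimesh.creation.icosphere(subdivisions=4, radius=0.5)
        step = 0.002
        clouds = []
        for zpos in (3.0, -3.0):
            target = np.array([0.0, 0.0, 0.0])
            pose = cap._look_at(np.array([0.0, 0.0, zpos]), target)
            cam = make_cam(pose=pose, depth_quantization_step=step)
            d = cap.quantize_depth(cap.render_depth(sph, cam), step)
            clouds.append(cap.backproject(d, cam))
        merged = cap.merge_clouds(clouds, dedup_radius=0.0)
        r = np.linalg.norm(merged.points, axis=1)
        # mesh facets lie slightly inside the analytic sphere; allow the
        # quantization step plus the facet sagitta
        assert np.abs(r - 0.5).max() < step + 2e-3

    def test_default_rig_coverage(self, adult_mesh, default_scan):
        """The default 15-camera rig samples >= 99% of the body surface
        to within 1 cm."""
        _, merged = default_scan
        samples = adult_mesh.sample(30_000)
        dist, _ = cKDTree(merged.points).query(samples, workers=-1)
        assert (dist < 0.01).mean() >= 0.99


class TestReconstruction:
    def test_sphere_volume_within_two_percent(self, sphere_cloud):
        mesh = cap.reconstruct_surface(sphere_cloud, voxel=0.012)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(4 / 3 * math.pi * 0.125, rel=0.02)

    def test_hemisphere_structured_failure(self, sphere_cloud):
        upper = sphere_cloud.points[:, 2] > 0
        hemi = cap.OrientedPointCloud(
            sphere_cloud.points[upper], sphere_cloud.normals[upper], sphere_cloud.source[upper]
        )
        with pytest.raises(cap.ReconstructionError):
            cap.reconstruct_surface(hemi, voxel=0.012)

    def test_sparse_cloud_rejected(self):
        c = cap.OrientedPointCloud(np.zeros((10, 3)), np.ones((10, 3)), np.zeros(10))
        with pytest.raises(cap.ReconstructionError, match="sparse"):
            cap.reconstruct_surface(c)


class TestEndToEnd:
    def test_full_chain_volume(self, adult_mesh, default_scan):
        """render -> quantize 2 mm -> smooth -> merge -> reconstruct
        recovers the source volume within 3%."""
        fused, _ = default_scan
        assert fused.is_watertight
        assert fused.volume == pytest.approx(adult_mesh.volume, rel=0.03)

    def test_fused_points_near_surface(self, adult_mesh, default_scan):
        _, merged = default_scan
        rng = np.random.default_rng(0)
        sel = rng.choice(len(merged), 20_000, replace=False)
        samples = np.vstack([adult_mesh.vertices, adult_mesh.triangles_center])
        dist, _ = cKDTree(samples).query(merged.points[sel], workers=-1)
        assert np.percentile(dist, 99) < 0.002 + 0.012

    def test_quantization_monotonicity(self, adult_mesh):
        """Decreasing the quantization step does not worsen the
        end-to-end volume error (median over seeds)."""
        errs = {}
        for step in (0.008, 0.002):
            per_seed = []
            for seed in (0, 1):
                rig = cap.default_rig(width=256, height=144, quantization_step=step)
                fused, _ = cap.simulate_scan(adult_mesh, rig, seed=seed)
                per_seed.append(abs(fused.volume / adult_mesh.volume - 1.0))
            errs[step] = float(np.median(per_seed))
        assert errs[0.002] <= errs[0.008] + 0.002
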