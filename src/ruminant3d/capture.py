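"""Simulated one-shot multi-camera depth acquisition and fusion.

The chain mirrors a fixed rig of depth cameras triggered
simultaneously around the animal: per-camera depth rendering, depth
discretisation (the "staircase" artifact of stereo depth sensors),
edge-preserving smoothing, back-projection to oriented point clouds,
pairwise extrinsic calibration from checkerboard corners, merging into
a common frame, and watertight surface reconstruction from the fused
oriented cloud.

Stereo matching itself is not simulated: depth maps are rendered
directly from the source mesh, with additive Gaussian noise and
quantisation standing in for stereo error.  Depth values are
principal-axis (z) depths, the convention of real RGB-D sensors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from numba import njit
from scipy.spatial import cKDTree
from skimage import measure as sk_measure

__all__ = [
    "CameraModel",
    "RigConfig",
    "DepthMap",
    "OrientedPointCloud",
    "Pose",
    "ReconstructionError",
    "CalibrationError",
    "render_depth",
    "quantize_depth",
    "smooth_depth",
    "backproject",
    "calibrate_pair",
    "merge_clouds",
    "reconstruct_surface",
    "default_rig",
    "simulate_scan",
]


class ReconstructionError(RuntimeError):
    """Surface reconstruction failed (insufficient coverage or a
    non-watertight result)."""


class CalibrationError(ValueError):
    """Extrinsic calibration failed (degenerate corner geometry)."""


@dataclass
class Pose:
    """Rigid transform: ``x_out = rotation @ x_in + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.rotation.T

    def inverse(self) -> "Pose":
        return Pose(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "Pose") -> "Pose":
        """self o other: apply ``other`` first."""
        return Pose(self.rotation @ other.rotation, self.rotation @ other.translation + self.translation)


@dataclass
class CameraModel:
    """Pinhole depth camera.

    ``pose`` maps camera coordinates (z forward, x right, y down) to
    the world frame.  ``depth_quantization_step`` reproduces the
    discretised depth levels of stereo sensors; ``depth_noise_sd`` is
    additive Gaussian depth noise.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    pose: Pose = field(default_factory=Pose.identity)
    depth_min: float = 0.3
    depth_max: float = 4.0
    depth_quantization_step: float = 0.002
    depth_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be > 0")
        if self.depth_quantization_step < 0 or self.depth_noise_sd < 0:
            raise ValueError("quantization step and noise sd must be >= 0")
        R = self.pose.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not math.isclose(
            float(np.linalg.det(R)), 1.0, abs_tol=1e-8
        ):
            raise ValueError("camera pose rotation must be orthonormal with det +1")

    @property
    def position(self) -> np.ndarray:
        return self.pose.translation

    @property
    def optical_axis(self) -> np.ndarray:
        return self.pose.rotation[:, 2]


@dataclass
class RigConfig:
    """An ordered set of cameras sharing a world frame.

    By convention the common frame is the frame of the reference
    (upper) camera; ``reference_index`` names it.
    """

    cameras: list[CameraModel]
    reference_index: int = 0

    def __len__(self) -> int:
        return len(self.cameras)


@dataclass
class DepthMap:
    """Per-pixel z-depths (m) with a validity mask."""

    depth: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.depth.shape != self.valid.shape:
            raise ValueError("depth and validity mask shapes differ")

    def copy(self) -> "DepthMap":
        return DepthMap(self.depth.copy(), self.valid.copy())


@dataclass
class OrientedPointCloud:
    """World-frame points with unit normals and source-camera indices."""

    points: np.ndarray
    normals: np.ndarray
    source: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        self.source = np.asarray(self.source, dtype=int).reshape(-1)
        if not (len(self.points) == len(self.normals) == len(self.source)):
            raise ValueError("points, normals and source must have equal length")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# rendering


@njit(cache=False)
def _rasterize(tri: np.ndarray, fx: float, fy: float, cx: float, cy: float, zbuf: np.ndarray) -> None:
    """Perspective-correct z-buffer rasterisation of camera-frame
    triangles (exact depth for planar triangles via linear 1/z)."""
    H, W = zbuf.shape
    for i in range(tri.shape[0]):
        z0, z1, z2 = tri[i, 0, 2], tri[i, 1, 2], tri[i, 2, 2]
        if z0 <= 1e-6 or z1 <= 1e-6 or z2 <= 1e-6:
            continue  # behind or crossing the image plane
        u0 = fx * tri[i, 0, 0] / z0 + cx
        v0 = fy * tri[i, 0, 1] / z0 + cy
        u1 = fx * tri[i, 1, 0] / z1 + cx
        v1 = fy * tri[i, 1, 1] / z1 + cy
        u2 = fx * tri[i, 2, 0] / z2 + cx
        v2 = fy * tri[i, 2, 1] / z2 + cy
        area = (u1 - u0) * (v2 - v0) - (u2 - u0) * (v1 - v0)
        if abs(area) < 1e-12:
            continue
        umin = max(int(math.ceil(min(u0, u1, u2))), 0)
        umax = min(int(math.floor(max(u0, u1, u2))), W - 1)
        vmin = max(int(math.ceil(min(v0, v1, v2))), 0)
        vmax = min(int(math.floor(max(v0, v1, v2))), H - 1)
        if umin > umax or vmin > vmax:
            continue
        iz0, iz1, iz2 = 1.0 / z0, 1.0 / z1, 1.0 / z2
        inv_area = 1.0 / area
        for v in range(vmin, vmax + 1):
            for u in range(umin, umax + 1):
                w0 = ((u1 - u) * (v2 - v) - (u2 - u) * (v1 - v)) * inv_area
                w1 = ((u2 - u) * (v0 - v) - (u0 - u) * (v2 - v)) * inv_area
                w2 = 1.0 - w0 - w1
                if w0 < -1e-12 or w1 < -1e-12 or w2 < -1e-12:
                    continue
                z = 1.0 / (w0 * iz0 + w1 * iz1 + w2 * iz2)
                if z < zbuf[v, u]:
                    zbuf[v, u] = z

    return


def render_depth(
    mesh: trimesh.Trimesh, cam: CameraModel, rng: np.random.Generator | None = None
) -> DepthMap:
    """Render the z-depth map of ``mesh`` seen by ``cam``.

    Each valid pixel holds the z-depth of the first surface hit along
    its ray; rays that miss the mesh (or hit outside the camera's depth
    range) are invalid.  Gaussian depth noise is added when the camera
    declares a nonzero ``depth_noise_sd`` and an ``rng`` is supplied.
    A camera located inside the mesh yields an all-invalid map with a
    warning.
    """
    inv = cam.pose.inverse()
    if mesh.bounds is not None and trimesh.bounds.contains(mesh.bounds, [cam.position]).all():
        # inside test from the nearest vertices' outward normals
        dist, idx = cKDTree(mesh.vertices).query(cam.position, k=6)
        rel = cam.position - mesh.vertices[np.atleast_1d(idx)]
        signs = np.einsum("ij,ij->i", rel, mesh.vertex_normals[np.atleast_1d(idx)])
        if np.median(signs) < 0:
            warnings.warn("camera is inside the mesh; returning an all-invalid depth map")
            return DepthMap(
                np.zeros((cam.height, cam.width)), np.zeros((cam.height, cam.width), bool)
            )
    tri_cam = inv.apply(mesh.triangles.reshape(-1, 3)).reshape(-1, 3, 3)
    zbuf = np.full((cam.height, cam.width), np.inf)
    _rasterize(np.ascontiguousarray(tri_cam), cam.fx, cam.fy, cam.cx, cam.cy, zbuf)
    valid = np.isfinite(zbuf)
    depth = np.where(valid, zbuf, 0.0)
    if cam.depth_noise_sd > 0 and rng is not None:
        depth = depth + np.where(valid, rng.normal(0.0, cam.depth_noise_sd, depth.shape), 0.0)
    in_range = valid & (depth >= cam.depth_min) & (depth <= cam.depth_max)
    depth = np.where(in_range, depth, 0.0)
    return DepthMap(depth, in_range)


def quantize_depth(d: DepthMap, step: float) -> DepthMap:
    """Round valid depths to the nearest multiple of ``step`` (the
    staircase artifact); ``step = 0`` is the identity."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if step == 0:
        return d.copy()
    out = d.copy()
    out.depth[out.valid] = np.round(out.depth[out.valid] / step) * step
    return out


def smooth_depth(d: DepthMap, spatial_radius: int = 3, range_sigma: float = 0.006) -> DepthMap:
    """Edge-preserving (bilateral) depth smoothing.

    A joint spatial/range filter: each valid pixel is replaced by a
    Gaussian-weighted average of valid neighbours within
    ``spatial_radius`` pixels, down-weighted by depth difference with
    scale ``range_sigma``.  Staircase steps (comparable to
    ``range_sigma``) are averaged out; true depth discontinuities much
    larger than ``range_sigma`` are preserved.  The validity mask is
    unchanged.
    """
    if spatial_radius < 1:
        raise ValueError("spatial_radius must be >= 1")
    depth, valid = d.depth, d.valid
    sigma_s = max(spatial_radius / 1.5, 0.5)
    acc = np.zeros_like(depth)
    wacc = np.zeros_like(depth)
    H, W = depth.shape
    for dy in range(-spatial_radius, spatial_radius + 1):
        for dx in range(-spatial_radius, spatial_radius + 1):
            if dy * dy + dx * dx > spatial_radius * spatial_radius:
                continue
            ws = math.exp(-(dy * dy + dx * dx) / (2.0 * sigma_s * sigma_s))
            sy0, sy1 = max(0, dy), min(H, H + dy)
            ty0, ty1 = max(0, -dy), min(H, H - dy)
            sx0, sx1 = max(0, dx), min(W, W + dx)
            tx0, tx1 = max(0, -dx), min(W, W - dx)
            nb = depth[sy0:sy1, sx0:sx1]
            nv = valid[sy0:sy1, sx0:sx1]
            ctr = depth[ty0:ty1, tx0:tx1]
            diff = nb - ctr
            w = ws * np.exp(-(diff * diff) / (2.0 * range_sigma * range_sigma)) * nv
            acc[ty0:ty1, tx0:tx1] += w * nb
            wacc[ty0:ty1, tx0:tx1] += w
    out = d.copy()
    ok = valid & (wacc > 0)
    out.depth[ok] = acc[ok] / wacc[ok]
    return out


def backproject(d: DepthMap, cam: CameraModel, source_index: int = 0) -> OrientedPointCloud:
    """Lift a depth map to an oriented point cloud in the world frame.

    One point per valid pixel; normals are estimated from the local
    depth gradient and oriented toward the camera.  Pixels without
    enough valid neighbours fall back to the viewing direction.
    """
    H, W = d.depth.shape
    vv, uu = np.mgrid[0:H, 0:W]
    z = d.depth
    x = (uu - cam.cx) / cam.fx * z
    y = (vv - cam.cy) / cam.fy * z
    P = np.dstack([x, y, z])
    P[~d.valid] = np.nan

    du = np.full_like(P, np.nan)
    dv = np.full_like(P, np.nan)
    du[:, 1:-1] = (P[:, 2:] - P[:, :-2]) / 2.0
    dv[1:-1, :] = (P[2:, :] - P[:-2, :]) / 2.0
    n = np.cross(du.reshape(-1, 3), dv.reshape(-1, 3)).reshape(H, W, 3)
    norm = np.linalg.norm(n, axis=2)
    bad = ~np.isfinite(norm) | (norm < 1e-12)
    # fallback: unit vector from the point toward the camera
    ray = -P / np.linalg.norm(P, axis=2, keepdims=True)
    n = np.where(bad[..., None], ray, n / np.where(norm[..., None] > 0, norm[..., None], 1.0))
    # orient toward the camera (camera sits at the origin in this frame)
    flip = np.einsum("ijk,ijk->ij", n, -P) < 0
    n[flip] *= -1.0

    pts = P[d.valid]
    nrm = n[d.valid]
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    world_p = cam.pose.apply(pts)
    world_n = cam.pose.rotate(nrm)
    return OrientedPointCloud(world_p, world_n, np.full(len(world_p), source_index))


# ---------------------------------------------------------------------------
# calibration and merging


def calibrate_pair(board_points_cam_a: np.ndarray, board_points_cam_b: np.ndarray) -> Pose:
    """Relative pose of camera *a* with respect to camera *b* from
    corresponding checkerboard corners seen in both camera frames.

    Solves the orthogonal Procrustes (Kabsch) problem minimising
    ``|| R @ p_a + t - p_b ||^2``; the returned pose maps coordinates
    in frame *a* to frame *b*.  Raises :class:`CalibrationError` for
    fewer than 3 corners or (near-)collinear corner sets.
    """
    A = np.asarray(board_points_cam_a, dtype=float).reshape(-1, 3)
    B = np.asarray(board_points_cam_b, dtype=float).reshape(-1, 3)
    if A.shape != B.shape:
        raise CalibrationError("corner lists must have equal shapes")
    if len(A) < 3:
        raise CalibrationError("need at least 3 corresponding corners")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    scale = S[0] if S[0] > 0 else 1.0
    if S[1] / scale < 1e-8:
        raise CalibrationError(
            f"degenerate (collinear) corner geometry: singular values {S}"
        )
    D = np.diag([1.0, 1.0, float(np.sign(np.linalg.det(Vt.T @ U.T)))])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    return Pose(R, t)


def merge_clouds(
    clouds: list[OrientedPointCloud],
    poses: list[Pose] | None = None,
    dedup_radius: float = 0.005,
) -> OrientedPointCloud:
    """Transform every cloud into the common frame and concatenate.

    ``poses[i]`` maps cloud ``i`` into the common (reference-camera)
    frame; ``None`` means all clouds are already in one frame.  With a
    positive ``dedup_radius`` the merged cloud is thinned on a voxel
    grid of that size (one point kept per voxel).
    """
    if poses is None:
        poses = [Pose.identity()] * len(clouds)
    if len(poses) != len(clouds):
        raise ValueError(f"{len(clouds)} clouds but {len(poses)} poses")
    pts = np.vstack([T.apply(c.points) for c, T in zip(clouds, poses)])
    nrm = np.vstack([T.rotate(c.normals) for c, T in zip(clouds, poses)])
    src = np.concatenate([c.source for c in clouds])
    if dedup_radius and dedup_radius > 0 and len(pts):
        keys = np.floor(pts / dedup_radius).astype(np.int64)
        _, idx = np.unique(keys, axis=0, return_index=True)
        idx.sort()
        pts, nrm, src = pts[idx], nrm[idx], src[idx]
    return OrientedPointCloud(pts, nrm, src)


# ---------------------------------------------------------------------------
# surface reconstruction


def reconstruct_surface(
    cloud: OrientedPointCloud,
    voxel: float = 0.012,
    k_neighbors: int = 10,
    margin_voxels: int = 6,
    ground_plane_z: float | None = None,
    seal_iterations: int = 3,
    carve_views: list[tuple["DepthMap", "CameraModel"]] | None = None,
) -> trimesh.Trimesh:
    """Watertight mesh from a fused oriented point cloud.

    An implicit moving-least-squares signed distance is evaluated on a
    regular grid — for each grid node the Gaussian-weighted mean of
    ``dot(g - p_i, n_i)`` over the ``k`` nearest cloud points — and the
    zero level set is extracted with marching cubes.  The sign comes
    from the normals, so consistent camera-facing orientation is
    required.

    The inside/outside far field is obtained either by flood-filling
    the complement of a (morphologically sealed) occupancy band from
    the sampling boundary, or — when the source depth maps are given
    via ``carve_views`` — by space carving: a node counts as outside
    only if some camera observed empty space through it.  Carving is
    robust to self-occluded surface patches (e.g. the belly strip
    hidden by the legs), which it closes at the visual hull, much as
    screened Poisson reconstruction closes unscanned holes.  With
    ``ground_plane_z`` set, the animal is assumed to stand on an
    opaque floor at that height, which closes the unscannable
    undersides of the feet with flat caps.

    Raises :class:`ReconstructionError` when the cloud does not
    enclose any volume (e.g. a partial scan) or the extracted mesh is
    not watertight.
    """
    from scipy import ndimage

    if len(cloud) < 100:
        raise ReconstructionError(f"cloud far too sparse ({len(cloud)} points)")
    p = cloud.points
    lo = p.min(axis=0) - margin_voxels * voxel
    hi = p.max(axis=0) + margin_voxels * voxel
    if ground_plane_z is not None:
        lo[2] = ground_plane_z - 1.5 * voxel  # one node layer below the floor
    axes = [np.arange(lo[i], hi[i] + voxel, voxel) for i in range(3)]
    shape = tuple(len(a) for a in axes)

    # occupancy band around the cloud; the far field only needs a sign,
    # obtained by flood-filling the complement from the grid boundary
    ijk = np.clip(np.round((p - lo) / voxel).astype(int), 0, np.array(shape) - 1)
    occ = np.zeros(shape, dtype=bool)
    occ[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    occ = ndimage.binary_dilation(occ, iterations=2)
    subfloor = np.zeros(shape, dtype=bool)
    if ground_plane_z is not None:
        # the floor is opaque: everything below it is outside the body.
        # The threshold sits ~2 voxels above the floor: the wedge of air
        # under a curved foot around its contact point is never scanned,
        # and must not connect the body interior to the outside.  The
        # foot bottoms are flat-capped at this height instead.
        subfloor[:, :, axes[2] < ground_plane_z + 1.8 * voxel] = True
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    G = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    if carve_views is not None:
        free = _carve_free_space(G, shape, carve_views, voxel)
        # unknown space (never observed) counts as body only when it is
        # connected to the scanned surface band; isolated shadow pockets
        # far from the body are outside
        unknown = ~occ & ~free & ~subfloor
        # the body interior is the connected never-observed region that
        # contains the cloud centroid; other unknown pockets (camera
        # shadows on the floor, unobserved grid corners) lie outside
        # the scanned band and are treated as empty space
        labels, n_lab = ndimage.label(unknown)
        body_unknown = unknown
        if n_lab > 1:
            centroid_idx = tuple(
                np.clip(
                    np.round((p.mean(axis=0) - lo) / voxel).astype(int),
                    0,
                    np.array(shape) - 1,
                )
            )
            lab = labels[centroid_idx]
            if lab == 0:
                # centroid fell on the band/free space: take the unknown
                # component with the most contact with the surface band
                touch = ndimage.binary_dilation(occ, iterations=1) & unknown
                counts = np.bincount(labels[touch], minlength=n_lab + 1)
                counts[0] = 0
                lab = int(np.argmax(counts))
            body_unknown = labels == lab
        outside = ~occ & ~body_unknown
    else:
        seal = ndimage.binary_closing(occ, iterations=seal_iterations) if seal_iterations else occ
        border = np.zeros(shape, dtype=bool)
        for axis in range(3):
            sl = [slice(None)] * 3
            for end in (0, -1):
                sl[axis] = end
                border[tuple(sl)] = True
                sl[axis] = slice(None)
        floodable = ~seal & ~subfloor
        outside = ndimage.binary_propagation(border & floodable, mask=floodable)
    inside = ~occ & ~outside & ~subfloor
    # a genuinely closed scan encloses much more than its surface band
    if inside.sum() < 0.25 * occ.sum():
        raise ReconstructionError(
            "the oriented cloud does not enclose a volume at this "
            "resolution: partial scan or insufficient coverage "
            f"(interior {inside.sum()} vs band {occ.sum()} nodes)"
        )
    far = 4.0 * voxel
    F = np.where(inside, -far, far).astype(float).ravel()

    # near band: Gaussian-weighted MLS signed distance over k neighbours
    near = np.nonzero(occ.ravel())[0]
    tree = cKDTree(p)
    h = 1.5 * voxel
    chunk = 200_000
    for s in range(0, len(near), chunk):
        sel = near[s : s + chunk]
        g = G[sel]
        dist, idx = tree.query(g, k=k_neighbors, workers=-1)
        w = np.exp(-(dist**2) / (2.0 * h * h)) + 1e-12
        rel = g[:, None, :] - p[idx]
        sd = np.einsum("ijk,ijk->ij", rel, cloud.normals[idx])
        F[sel] = np.clip(np.sum(w * sd, axis=1) / np.sum(w, axis=1), -far, far)
    F = F.reshape(shape)
    if ground_plane_z is not None:
        F[subfloor] = far  # flat caps where the body meets the floor
    try:
        verts, faces, _, _ = sk_measure.marching_cubes(F, level=0.0, spacing=(voxel,) * 3)
    except ValueError as e:
        raise ReconstructionError(f"no zero level set found: {e}") from e
    verts += lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if not mesh.is_watertight:
        parts = [m for m in mesh.split(only_watertight=True)]
        if not parts:
            raise ReconstructionError("reconstructed surface is not watertight")
        mesh = max(parts, key=lambda m: abs(m.volume))
    elif mesh.body_count > 1:
        mesh = max(mesh.split(only_watertight=True), key=lambda m: abs(m.volume))
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _carve_free_space(
    G: np.ndarray, shape: tuple, views: list[tuple["DepthMap", "CameraModel"]], voxel: float
) -> np.ndarray:
    """Space carving: nodes some camera observed empty space through.

    A node is free if its projection falls on a depth pixel and lies
    at least two voxels in front of the measured surface; a pixel with
    no return means the whole ray is empty within the camera's range.
    """
    free = np.zeros(len(G), dtype=bool)
    for d, cam in views:
        q = cam.pose.inverse().apply(G)
        z = q[:, 2]
        ok = z > 1e-6
        u = np.round(cam.fx * q[:, 0] / np.where(ok, z, 1.0) + cam.cx).astype(int)
        v = np.round(cam.fy * q[:, 1] / np.where(ok, z, 1.0) + cam.cy).astype(int)
        ok &= (u >= 0) & (u < cam.width) & (v >= 0) & (v < cam.height)
        uu = np.where(ok, u, 0)
        vv = np.where(ok, v, 0)
        hit = d.valid[vv, uu]
        free |= ok & hit & (z < d.depth[vv, uu] - 2.0 * voxel)
        free |= ok & ~hit & (z < cam.depth_max)
    return free.reshape(shape)


# ---------------------------------------------------------------------------
# the default rig


def _look_at(position: np.ndarray, target: np.ndarray) -> Pose:
    """Camera pose looking from ``position`` toward ``target`` (camera
    z forward, x right, y down; world z is up)."""
    z = target - position
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    x = np.cross(z, up)
    if np.linalg.norm(x) < 1e-8:  # looking straight down/up
        x = np.array([1.0, 0.0, 0.0])
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    if np.linalg.det(R) < 0:
        R[:, 0] *= -1
    return Pose(R, position)


def default_rig(
    width: int = 848,
    height: int = 480,
    radius: float = 1.8,
    center_height: float = 0.9,
    arc_x: tuple[float, ...] = (-1.05, 0.0, 1.05),
    arc_angles_deg: tuple[float, ...] = (-115.0, -57.5, 0.0, 57.5, 115.0),
    quantization_step: float = 0.002,
    depth_noise_sd: float = 0.0,
) -> RigConfig:
    """The default 15-camera gantry: three transverse arcs of five
    cameras each (left low/high, top, right high/low), all aimed at the
    animal axis.  The top camera of the middle arc is the reference
    (common-frame) camera.

    Camera poses here are declared rig design, not a reproduction of
    any particular hardware layout.
    """
    f = 0.65 * width
    cams = []
    for xi in arc_x:
        for ang in arc_angles_deg:
            a = math.radians(ang)
            pos = np.array([xi, 0.0, center_height]) + radius * np.array(
                [0.0, math.sin(a), math.cos(a)]
            )
            # low cameras aim below the belly so their field of view
            # sweeps the floor next to the animal; without this the
            # floor strip in the body's shadow is never observed.  End
            # arcs aim inboard to keep the head and tail in view.
            target = np.array(
                [0.7 * xi, 0.0, 0.40 if abs(ang) > 100 else center_height]
            )
            cams.append(
                CameraModel(
                    fx=f,
                    fy=f,
                    cx=width / 2.0,
                    cy=height / 2.0,
                    width=width,
                    height=height,
                    pose=_look_at(pos, target),
                    depth_quantization_step=quantization_step,
                    depth_noise_sd=depth_noise_sd,
                )
            )
    # reference camera: the top camera of the middle arc
    ref = len(arc_angles_deg) * (len(arc_x) // 2) + list(arc_angles_deg).index(0.0)
    return RigConfig(cameras=cams, reference_index=ref)


def simulate_scan(
    mesh: trimesh.Trimesh,
    rig: RigConfig,
    smooth_radius: int = 3,
    range_sigma: float | None = None,
    dedup_radius: float = 0.005,
    voxel: float = 0.012,
    seed: int | None = None,
) -> tuple[trimesh.Trimesh, OrientedPointCloud]:
    """Run the full acquisition chain on a source mesh.

    render -> quantize -> smooth -> backproject per camera, merge all
    clouds (poses are exact here; calibration error is studied
    separately), reconstruct.  Returns the fused mesh and the merged
    cloud.  ``range_sigma`` defaults to 3x the quantisation step.
    """
    rng = np.random.default_rng(seed)
    clouds = []
    views = []
    for i, cam in enumerate(rig.cameras):
        d = render_depth(mesh, cam, rng=rng)
        if not d.valid.any():
            continue
        step = cam.depth_quantization_step
        d = quantize_depth(d, step)
        rs = range_sigma if range_sigma is not None else max(3.0 * step, 1e-4)
        d = smooth_depth(d, spatial_radius=smooth_radius, range_sigma=rs)
        clouds.append(backproject(d, cam, source_index=i))
        views.append((d, cam))
    merged = merge_clouds(clouds, dedup_radius=dedup_radius)
    fused = reconstruct_surface(
        merged, voxel=voxel, ground_plane_z=0.0, carve_views=views
    )
    return fused, merged
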