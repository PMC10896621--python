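"""File I/O: meshes (PLY/OBJ via trimesh), landmark tables (CSV),
camera rigs (YAML) and depth maps (16-bit PGM, millimetres).

Landmark CSV layout: columns (landmark_name, x, y, z), with the
longitudinal stations stored as pseudo-landmarks (their x coordinate
carries the station; y and z are blank).  Study-level files add
subject/session/repeat columns.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import trimesh
import yaml

from .capture import CameraModel, DepthMap, Pose, RigConfig
from .morphometry import FeaturePoints, LANDMARK_NAMES, STATION_NAMES

__all__ = [
    "save_mesh",
    "load_mesh",
    "save_landmarks",
    "load_landmarks",
    "save_rig",
    "load_rig",
    "save_depth_pgm",
    "load_depth_pgm",
]


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write a mesh as binary PLY or OBJ, by file extension."""
    mesh.export(str(path))


def load_mesh(path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), force="mesh")
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a triangle mesh")
    return mesh


def save_landmarks(fp: FeaturePoints, path) -> None:
    rows = []
    for name in LANDMARK_NAMES:
        v = getattr(fp, name)
        if v is not None:
            rows.append(dict(landmark_name=name, x=v[0], y=v[1], z=v[2]))
    for name in STATION_NAMES:
        s = getattr(fp, name)
        if s is not None:
            rows.append(dict(landmark_name=name, x=s, y=math.nan, z=math.nan))
    pd.DataFrame(rows).to_csv(path, index=False)


def load_landmarks(path) -> FeaturePoints:
    df = pd.read_csv(path)
    kwargs = {}
    for _, row in df.iterrows():
        name = row["landmark_name"]
        if name in STATION_NAMES:
            kwargs[name] = float(row["x"])
        elif name in LANDMARK_NAMES:
            kwargs[name] = np.array([row["x"], row["y"], row["z"]], dtype=float)
    return FeaturePoints(**kwargs)


def save_rig(rig: RigConfig, path) -> None:
    """Rig as YAML: per camera intrinsics plus pose with the rotation as
    a scalar-last unit quaternion (x, y, z, w) and translation in m."""
    cams = []
    for c in rig.cameras:
        M = np.eye(4)
        M[:3, :3] = c.pose.rotation
        q = trimesh.transformations.quaternion_from_matrix(M)  # (w, x, y, z)
        cams.append(
            dict(
                fx=float(c.fx),
                fy=float(c.fy),
                cx=float(c.cx),
                cy=float(c.cy),
                width=int(c.width),
                height=int(c.height),
                quaternion_xyzw=[float(q[1]), float(q[2]), float(q[3]), float(q[0])],
                translation=[float(t) for t in c.pose.translation],
                depth_min=float(c.depth_min),
                depth_max=float(c.depth_max),
                depth_quantization_step=float(c.depth_quantization_step),
                depth_noise_sd=float(c.depth_noise_sd),
            )
        )
    with open(path, "w") as fh:
        yaml.safe_dump(
            dict(reference_index=rig.reference_index, cameras=cams), fh, sort_keys=False
        )


def load_rig(path) -> RigConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cams = []
    for c in data["cameras"]:
        x, y, z, w = c["quaternion_xyzw"]
        R = trimesh.transformations.quaternion_matrix([w, x, y, z])[:3, :3]
        cams.append(
            CameraModel(
                fx=c["fx"],
                fy=c["fy"],
                cx=c["cx"],
                cy=c["cy"],
                width=c["width"],
                height=c["height"],
                pose=Pose(R, np.array(c["translation"], dtype=float)),
                depth_min=c.get("depth_min", 0.3),
                depth_max=c.get("depth_max", 4.0),
                depth_quantization_step=c.get("depth_quantization_step", 0.0),
                depth_noise_sd=c.get("depth_noise_sd", 0.0),
            )
        )
    return RigConfig(cameras=cams, reference_index=data.get("reference_index", 0))


def save_depth_pgm(d: DepthMap, path) -> None:
    """16-bit ASCII PGM in millimetres; invalid pixels are 0."""
    mm = np.where(d.valid, np.clip(np.round(d.depth * 1000.0), 1, 65535), 0).astype(int)
    H, W = mm.shape
    with open(path, "w") as fh:
        fh.write(f"P2\n{W} {H}\n65535\n")
        for row in mm:
            fh.write(" ".join(str(v) for v in row) + "\n")


def load_depth_pgm(path) -> DepthMap:
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if tokens[0] != "P2":
        raise ValueError("expected an ASCII PGM (P2) depth file")
    W, H, _maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    mm = np.array(tokens[4 : 4 + W * H], dtype=float).reshape(H, W)
    return DepthMap(mm / 1000.0, mm > 0)
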