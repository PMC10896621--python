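"""Shared fixtures: analytic solids and session-scoped synthetic cows.

Heavy objects (the adult cow mesh, a full simulated scan) are built
once per session and shared read-only across tests.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
import trimesh

from ruminant3d import capture, herd, morphometry


@pytest.fixture(scope="session")
def adult_params():
    return herd.adult_cow_params()


@pytest.fixture(scope="session")
def adult_mesh(adult_params):
    return herd.make_cow_mesh(adult_params)


@pytest.fixture(scope="session")
def adult_landmarks(adult_params):
    return herd.true_landmarks(adult_params)


@pytest.fixture(scope="session")
def adult_traits(adult_mesh, adult_landmarks):
    return morphometry.measure_all(adult_mesh, adult_landmarks)


@pytest.fixture(scope="session")
def default_scan(adult_mesh):
    """Full simulated acquisition of the adult cow with the default
    15-camera rig at a moderate image size (fused mesh, merged cloud)."""
    rig = capture.default_rig(width=424, height=240)
    fused, merged = capture.simulate_scan(adult_mesh, rig, seed=0)
    return fused, merged


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=0.5)


@pytest.fixture()
def unit_cube():
    return trimesh.creation.box(extents=[1.0, 1.0, 1.0])


@pytest.fixture()
def x_cylinder():
    """Cylinder of radius 0.3 and length 2 with its axis along x."""
    cyl = trimesh.creation.cylinder(radius=0.3, height=2.0, sections=256)
    cyl.apply_transform(trimesh.transformations.rotation_matrix(math.pi / 2, [0, 1, 0]))
    return cyl


@pytest.fixture(scope="session")
def sphere_cloud():
    """Dense oriented point cloud of a 0.5 m sphere with 0.5 mm noise."""
    rng = np.random.default_rng(2)
    n = 60_000
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = 0.5 * v + rng.normal(0.0, 0.0005, (n, 3))
    return capture.OrientedPointCloud(pts, v, np.zeros(n))
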