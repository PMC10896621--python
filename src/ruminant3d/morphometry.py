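"""Mesh morphometry: the nine cattle body traits plus volumes and surfaces.

All geometry lives in a right-handed frame with ``x`` along the animal
(positive toward the head), ``z`` vertical, and the ground plane at
``z = 0``.  Traits are computed from a watertight triangle mesh together
with a set of named anatomical feature points; cutting planes and girth
stations are ``x`` coordinates.

Trait glossary (units are metres unless noted):

========  ==========================================================
WH        withers height — vertical distance from the ground plane to
          the withers landmark
HW        hip width — distance between left and right hip landmarks
WB        buttocks width — distance between the pin-bone landmarks
CD        chest depth — vertical extent of the torso cross-section at
          the chest station
HG        heart girth — taut-tape circumference of the torso at the
          chest station (convex-hull perimeter)
AC        abdominal circumference — girth at the abdomen station
DL        diagonal length — mean of left/right buttock-tip to
          shoulder-tip distances
PV / PS   partial volume (m^3) / surface (m^2) between the rump and
          shoulder cutting planes (head and neck excluded)
TV / TS   total volume (m^3) / surface (m^2) of the complete mesh
========  ==========================================================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable

import numpy as np
import trimesh
from shapely.geometry import MultiPoint

__all__ = [
    "FeaturePoints",
    "CrossSection",
    "TraitVector",
    "MeshDefectError",
    "mesh_volume",
    "mesh_area",
    "clip_halfspace",
    "clip_partial_body",
    "cross_section",
    "girth",
    "measure_all",
]

LANDMARK_NAMES = (
    "withers",
    "hip_left",
    "hip_right",
    "pin_left",
    "pin_right",
    "shoulder_tip_left",
    "shoulder_tip_right",
    "buttock_tip_left",
    "buttock_tip_right",
)

STATION_NAMES = ("chest_station", "abdomen_station", "shoulder_plane", "rump_plane")


class MeshDefectError(ValueError):
    """Raised when a mesh violates the watertightness contract."""


@dataclass
class FeaturePoints:
    """Named anatomical landmarks plus longitudinal stations.

    Landmarks are 3-vectors in metres; stations are scalar ``x``
    coordinates of transverse cutting planes.  A missing landmark is
    ``None`` and only suppresses the traits that need it.
    """

    withers: np.ndarray | None = None
    hip_left: np.ndarray | None = None
    hip_right: np.ndarray | None = None
    pin_left: np.ndarray | None = None
    pin_right: np.ndarray | None = None
    shoulder_tip_left: np.ndarray | None = None
    shoulder_tip_right: np.ndarray | None = None
    buttock_tip_left: np.ndarray | None = None
    buttock_tip_right: np.ndarray | None = None
    chest_station: float | None = None
    abdomen_station: float | None = None
    shoulder_plane: float | None = None
    rump_plane: float | None = None

    def __post_init__(self) -> None:
        for name in LANDMARK_NAMES:
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float).reshape(3))
        stations = [getattr(self, s) for s in STATION_NAMES]
        if all(s is not None for s in stations):
            chest, abdomen, shoulder, rump = stations
            if not (rump < abdomen < chest < shoulder):
                raise ValueError(
                    "stations must be ordered rump < abdomen < chest < shoulder "
                    f"along +x, got rump={rump}, abdomen={abdomen}, "
                    f"chest={chest}, shoulder={shoulder}"
                )

    def transform(self, matrix: np.ndarray) -> "FeaturePoints":
        """Apply a 4x4 homogeneous transform to every landmark.

        Stations are only meaningful for transforms that keep the
        longitudinal axis on ``x``; they are mapped through the
        transform's action on the x axis.
        """
        matrix = np.asarray(matrix, dtype=float)
        out = {}
        for name in LANDMARK_NAMES:
            v = getattr(self, name)
            if v is not None:
                out[name] = matrix[:3, :3] @ v + matrix[:3, 3]
        for name in STATION_NAMES:
            s = getattr(self, name)
            if s is not None:
                p = matrix[:3, :3] @ np.array([s, 0.0, 0.0]) + matrix[:3, 3]
                out[name] = float(p[0])
        return FeaturePoints(**out)

    def mirrored(self) -> "FeaturePoints":
        """Left/right mirror (y -> -y), swapping paired landmark names."""
        out = {}
        for name in LANDMARK_NAMES:
            v = getattr(self, name)
            if v is None:
                continue
            w = v * np.array([1.0, -1.0, 1.0])
            if name.endswith("_left"):
                out[name[: -len("_left")] + "_right"] = w
            elif name.endswith("_right"):
                out[name[: -len("_right")] + "_left"] = w
            else:
                out[name] = w
        for name in STATION_NAMES:
            s = getattr(self, name)
            if s is not None:
                out[name] = s
        return FeaturePoints(**out)


@dataclass
class CrossSection:
    """Planar section of a mesh at a longitudinal station.

    ``contours`` are closed polylines as (n, 2) arrays in the plane's
    (y, z) coordinates; ``torso_index`` flags the contour that contains
    the dorsal-most (highest z) point, i.e. the body rather than a leg.
    """

    station: float
    contours: list[np.ndarray]
    torso_index: int

    @property
    def torso(self) -> np.ndarray:
        return self.contours[self.torso_index]


@dataclass
class TraitVector:
    """The morphological trait set, in metres / m^2 / m^3."""

    wh: float = math.nan
    hw: float = math.nan
    wb: float = math.nan
    cd: float = math.nan
    hg: float = math.nan
    ac: float = math.nan
    dl: float = math.nan
    ps: float = math.nan
    ts: float = math.nan
    pv: float = math.nan
    tv: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def scaled(self, s: float) -> "TraitVector":
        """Traits after uniform length scaling by ``s``."""
        return TraitVector(
            **{
                k: v * (s**3 if k in ("pv", "tv") else s**2 if k in ("ps", "ts") else s)
                for k, v in self.as_dict().items()
            }
        )

    def volumes_litres(self) -> dict[str, float]:
        """Reporting-layer conversion of the volume entries to litres."""
        return {"pv_L": 1000.0 * self.pv, "tv_L": 1000.0 * self.tv}


# ---------------------------------------------------------------------------
# volume / area


def _require_watertight(mesh: trimesh.Trimesh) -> None:
    if not mesh.is_watertight:
        edges = mesh.edges_sorted
        unique, counts = np.unique(edges, axis=0, return_counts=True)
        n_open = int(np.sum(counts != 2))
        raise MeshDefectError(
            f"mesh is not watertight: {n_open} edges not shared by exactly "
            f"2 faces ({len(mesh.faces)} faces total)"
        )


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Volume of a watertight, outward-oriented mesh (divergence theorem).

    Each triangle contributes the signed volume of the tetrahedron it
    spans with the origin, ``det(v0, v1, v2) / 6``; the origin-dependent
    parts cancel over a closed surface, making the sum translation- and
    rotation-invariant.
    """
    _require_watertight(mesh)
    tri = mesh.triangles  # (n, 3, 3)
    v = float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)
    if v < 0:
        # consistently inward-oriented closed surface: flip sign
        v = -v
    return v


def mesh_area(mesh: trimesh.Trimesh) -> float:
    """Total surface area: sum of triangle areas (degenerate faces count 0)."""
    tri = mesh.triangles
    a = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    return float(a.sum())


# ---------------------------------------------------------------------------
# plane clipping with fan capping

_PLANE_TOL = 1e-9


def _chain_loops(segments: np.ndarray) -> list[np.ndarray]:
    """Chain unordered 2-point segments into closed loops (indices into a
    deduplicated vertex table built with an exact-coordinate key)."""
    if len(segments) == 0:
        return []
    key2idx: dict[bytes, int] = {}
    verts: list[np.ndarray] = []

    def vid(p: np.ndarray) -> int:
        k = np.round(p / _PLANE_TOL).astype(np.int64).tobytes()
        if k not in key2idx:
            key2idx[k] = len(verts)
            verts.append(p)
        return key2idx[k]

    edges = [(vid(s[0]), vid(s[1])) for s in segments]
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        if a == b:
            continue
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    used = set()
    loops = []
    for a, b in edges:
        if a == b or (a, b) in used or (b, a) in used:
            continue
        loop = [a, b]
        used.add((a, b))
        while loop[-1] != loop[0]:
            cur, prev = loop[-1], loop[-2]
            nxts = [n for n in adj.get(cur, []) if n != prev and (cur, n) not in used and (n, cur) not in used]
            if not nxts:
                break
            nxt = nxts[0]
            used.add((cur, nxt))
            loop.append(nxt)
        if loop[-1] == loop[0] and len(loop) > 3:
            loops.append(np.array([verts[i] for i in loop[:-1]]))
    return loops


def clip_halfspace(
    mesh: trimesh.Trimesh, plane_origin, plane_normal, cap: bool = True
) -> trimesh.Trimesh:
    """Keep the part of ``mesh`` with ``dot(p - origin, normal) <= 0``,
    capping each cut opening with a planar triangle fan around its
    centroid.

    The input must be watertight; the output is watertight again (the
    fan caps close every boundary loop produced by the cut).
    """
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    o = np.asarray(plane_origin, dtype=float)
    V = mesh.vertices.view(np.ndarray)
    F = mesh.faces.view(np.ndarray)
    d = (V - o) @ n
    # snap near-plane vertices exactly onto the plane to avoid slivers
    d[np.abs(d) < _PLANE_TOL] = 0.0

    keep_v = d <= 0.0
    side = np.sign(d).astype(int)  # -1 keep, 0 on-plane, +1 discard
    fs = side[F]

    full_keep = np.all(fs <= 0, axis=1)
    full_drop = np.all(fs >= 0, axis=1) & np.any(fs > 0, axis=1)
    crossing = ~full_keep & ~full_drop

    new_faces: list[list[int]] = [list(f) for f in F[full_keep]]
    verts: list[np.ndarray] = [v for v in V]
    cut_segments: list[np.ndarray] = []
    edge_cache: dict[tuple[int, int], int] = {}

    def cut_point(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key not in edge_cache:
            t = d[i] / (d[i] - d[j])
            p = V[i] + t * (V[j] - V[i])
            p = p - ((p - o) @ n) * n  # project exactly onto the plane
            edge_cache[key] = len(verts)
            verts.append(p)
        return edge_cache[key]

    for f in F[crossing]:
        s = side[f]
        below = [int(f[k]) for k in range(3) if s[k] < 0]
        on = [int(f[k]) for k in range(3) if s[k] == 0]
        above = [int(f[k]) for k in range(3) if s[k] > 0]
        # preserve winding: rotate face so pattern handling keeps orientation
        order = [int(i) for i in f]
        ss = [side[i] for i in order]
        if len(below) == 1 and len(above) == 2:
            while not (ss[0] < 0):
                order = order[1:] + order[:1]
                ss = ss[1:] + ss[:1]
            a, b, c = order  # a below, b/c above
            pab, pac = cut_point(a, b), cut_point(a, c)
            new_faces.append([a, pab, pac])
            cut_segments.append(np.array([verts[pab], verts[pac]]))
        elif len(below) == 2 and len(above) == 1:
            while not (ss[0] > 0):
                order = order[1:] + order[:1]
                ss = ss[1:] + ss[:1]
            a, b, c = order  # a above, b/c below
            pab, pac = cut_point(a, b), cut_point(a, c)
            new_faces.append([b, c, pab])
            new_faces.append([c, pac, pab])
            cut_segments.append(np.array([verts[pac], verts[pab]]))
        elif len(on) == 1 and len(below) == 1 and len(above) == 1:
            while not (ss[0] == 0):
                order = order[1:] + order[:1]
                ss = ss[1:] + ss[:1]
            a, b, c = order
            if side[b] < 0:  # b below, c above
                pbc = cut_point(b, c)
                new_faces.append([a, b, pbc])
                cut_segments.append(np.array([verts[pbc], verts[a]]))
            else:  # b above, c below
                pbc = cut_point(b, c)
                new_faces.append([a, pbc, c])
                cut_segments.append(np.array([verts[a], verts[pbc]]))
        # remaining patterns (on==3, or on==2 with the third vertex on
        # one side) never reach here: they classify as full keep/drop

    # kept faces with an edge exactly in the plane contribute that edge
    # to the cap boundary (the face on the other side was dropped)
    for f in F[full_keep]:
        s = side[f]
        if np.count_nonzero(s == 0) == 2:
            a, b = (int(f[k]) for k in range(3) if s[k] == 0)
            cut_segments.append(np.array([V[a], V[b]]))

    Vn = np.array(verts)
    if cap and cut_segments:
        loops = _chain_loops(np.array(cut_segments))
        # plane basis (u, v) with u x v = n, for loop orientation
        u = np.cross(n, [1.0, 0.0, 0.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(n, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        for loop in loops:
            centroid = loop.mean(axis=0)
            p2 = np.column_stack([(loop - centroid) @ u, (loop - centroid) @ v])
            signed_area = 0.5 * float(
                np.sum(p2[:, 0] * np.roll(p2[:, 1], -1) - np.roll(p2[:, 0], -1) * p2[:, 1])
            )
            ci = len(Vn)
            Vn = np.vstack([Vn, centroid])
            base = len(Vn)
            Vn = np.vstack([Vn, loop])
            m = len(loop)
            # orient each fan triangle so the cap's normal points along +n
            # (outward of the kept half-space)
            ccw = signed_area > 0
            for k in range(m):
                a, b = base + k, base + (k + 1) % m
                new_faces.append([ci, a, b] if ccw else [ci, b, a])

    out = trimesh.Trimesh(vertices=Vn, faces=np.array(new_faces, dtype=np.int64), process=True)
    out.remove_unreferenced_vertices()
    return out


def clip_partial_body(
    mesh: trimesh.Trimesh, shoulder_plane: float, rump_plane: float
) -> trimesh.Trimesh:
    """Body region between the rump and shoulder cutting planes.

    The planes are orthogonal to the longitudinal (x) axis; the cut
    openings are capped so partial volume and surface are well defined.
    Planes beyond the mesh extent degrade gracefully to a no-op with a
    warning; an inverted plane order is an error.
    """
    if not shoulder_plane > rump_plane:
        raise ValueError(
            f"shoulder plane ({shoulder_plane}) must be ahead of rump plane ({rump_plane})"
        )
    _require_watertight(mesh)
    xmin, xmax = mesh.bounds[0][0], mesh.bounds[1][0]
    out = mesh
    if shoulder_plane >= xmax and rump_plane <= xmin:
        warnings.warn("cutting planes lie outside the mesh; returning the full mesh")
        return out
    if shoulder_plane < xmax:
        out = clip_halfspace(out, [shoulder_plane, 0, 0], [1.0, 0, 0])
    if rump_plane > xmin:
        out = clip_halfspace(out, [rump_plane, 0, 0], [-1.0, 0, 0])
    return out


# ---------------------------------------------------------------------------
# cross-sections and girth


def cross_section(mesh: trimesh.Trimesh, station: float, tol: float = 1e-6) -> CrossSection:
    """Closed contours of the mesh cut by the transverse plane x = station.

    Contours are returned in the plane's (y, z) coordinates.  The
    contour containing the dorsal-most point is flagged as the torso;
    the others are typically legs.
    """
    path = mesh.section(plane_origin=[station, 0.0, 0.0], plane_normal=[1.0, 0.0, 0.0])
    if path is None:
        raise ValueError(f"plane x = {station} does not intersect the mesh")
    contours = []
    for poly in path.discrete:
        poly = np.asarray(poly)
        if np.linalg.norm(poly[0] - poly[-1]) < 1e-8:
            poly = poly[:-1]
        if len(poly) < 3 or np.ptp(poly[:, 1:], axis=0).max() < tol:
            continue  # tangent/degenerate sliver
        contours.append(poly[:, 1:3])  # (y, z)
    if not contours:
        raise ValueError(f"section at x = {station} is degenerate (tangent plane?)")
    torso_index = int(np.argmax([c[:, 1].max() for c in contours]))
    return CrossSection(station=float(station), contours=contours, torso_index=torso_index)


def contour_length(contour: np.ndarray) -> float:
    """Perimeter of a closed polyline given as an (n, 2) array."""
    d = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.linalg.norm(d, axis=1).sum())


def girth(section: CrossSection) -> float:
    """Taut-tape girth: convex-hull perimeter of the torso contour.

    A physical tape bridges concavities, so the measure is the perimeter
    of the planar convex hull, which is never larger than the raw
    contour length and is invariant to in-plane rotation.
    """
    hull = MultiPoint([tuple(p) for p in section.torso]).convex_hull
    return float(hull.length)


# ---------------------------------------------------------------------------
# the full trait vector


def _dist(a: np.ndarray | None, b: np.ndarray | None) -> float:
    if a is None or b is None:
        return math.nan
    return float(np.linalg.norm(a - b))


def measure_all(mesh: trimesh.Trimesh, fp: FeaturePoints) -> TraitVector:
    """Compute every trait available from the mesh and feature points.

    Missing landmarks or stations yield NaN for the traits that depend
    on them; all other traits are still computed.
    """
    t = TraitVector()
    if fp.withers is not None:
        t.wh = float(fp.withers[2])  # height above the ground plane z = 0
    t.hw = _dist(fp.hip_left, fp.hip_right)
    t.wb = _dist(fp.pin_left, fp.pin_right)
    dl_l = _dist(fp.buttock_tip_left, fp.shoulder_tip_left)
    dl_r = _dist(fp.buttock_tip_right, fp.shoulder_tip_right)
    if not (math.isnan(dl_l) or math.isnan(dl_r)):
        t.dl = 0.5 * (dl_l + dl_r)

    t.tv = mesh_volume(mesh)
    t.ts = mesh_area(mesh)

    if fp.chest_station is not None:
        sec = cross_section(mesh, fp.chest_station)
        torso = sec.torso
        t.cd = float(torso[:, 1].max() - torso[:, 1].min())
        t.hg = girth(sec)
    if fp.abdomen_station is not None:
        t.ac = girth(cross_section(mesh, fp.abdomen_station))
    if fp.shoulder_plane is not None and fp.rump_plane is not None:
        partial = clip_partial_body(mesh, fp.shoulder_plane, fp.rump_plane)
        t.pv = mesh_volume(partial)
        # PS is the scanned body surface between the planes: the flat
        # closure caps exist only to make PV well defined and are excluded.
        t.ps = mesh_area(partial) - _cap_area(
            partial, (fp.shoulder_plane, fp.rump_plane)
        )
    return t


def _cap_area(mesh: trimesh.Trimesh, plane_xs: Iterable[float], tol: float = 1e-7) -> float:
    """Area of faces lying flat in any of the transverse planes."""
    tri = mesh.triangles
    area = 0.0
    for x0 in plane_xs:
        in_plane = np.all(np.abs(tri[:, :, 0] - x0) < tol, axis=1)
        if in_plane.any():
            t = tri[in_plane]
            area += float(
                0.5
                * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1).sum()
            )
    return area
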