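"""Parametric cow bodies with known ground truth, and study simulation.

The body is an implicit surface: a lofted superellipsoid torso, four
capsule legs, an optional neck/head capsule and a withers bump, joined
by a smooth minimum and meshed with marching cubes.  This is about the
simplest watertight family whose traits have semi-analytic ground
truth while spanning the size range of adult Holstein cows (total
volume roughly 0.58-0.77 m^3, withers height 1.38-1.50 m).

The module also instantiates the validation study designs used for
device assessment: repeated landmark identification on a single
acquisition (repeatability) and repeated acquisition sessions with the
animal in slightly different postures (reproducibility), with a
layered noise model that keeps the two sources separate.

Frame convention: x longitudinal (+x toward the head), z vertical,
ground plane z = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import trimesh
from skimage import measure as sk_measure

from . import morphometry, prediction
from .morphometry import FeaturePoints, TraitVector

__all__ = [
    "CowParams",
    "NoiseModel",
    "StudyDesign",
    "StudyRecord",
    "CowBody",
    "adult_cow_params",
    "heifer_params",
    "ellipsoid_params",
    "make_cow_mesh",
    "true_landmarks",
    "true_traits",
    "generate_study",
    "measure_study",
    "scale_weight",
    "make_herd",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class CowParams:
    """Geometric parameters of one synthetic animal (metres / radians).

    ``torso_shape_exponents`` are the superellipsoid exponents
    (cross-section, profile): (1, 1) is a plain ellipsoid, values below
    1 bulge toward a box.  Station fractions position the transverse
    measurement planes along the torso, as fractions of body length
    from tail (0) to head (1), and must satisfy
    ``rump_plane_frac < abdomen_station_frac < chest_station_frac <
    shoulder_plane_frac``.
    """

    torso_half_length: float = 0.93
    torso_half_width: float = 0.36
    torso_half_height: float = 0.40
    torso_shape_exponents: tuple[float, float] = (0.85, 1.0)
    torso_center_height: float = 0.955
    leg_length: float = 0.92
    leg_radius: float = 0.095
    n_legs: int = 4
    neck_head_enabled: bool = True
    head_pitch: float = 0.0
    head_length: float = 0.78
    head_radius: float = 0.155
    withers_bump_height: float = 0.045
    withers_lever: float = 0.25
    tail_enabled: bool = True
    tail_radius: float = 0.035
    chest_station_frac: float = 0.62
    abdomen_station_frac: float = 0.42
    shoulder_plane_frac: float = 0.80
    rump_plane_frac: float = 0.06
    mesh_resolution: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "torso_half_length",
            "torso_half_width",
            "torso_half_height",
            "torso_center_height",
            "leg_length",
            "leg_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        fr = (
            self.rump_plane_frac,
            self.abdomen_station_frac,
            self.chest_station_frac,
            self.shoulder_plane_frac,
        )
        if not (0 <= fr[0] < fr[1] < fr[2] < fr[3] <= 1):
            raise ValueError(
                "station fractions must be strictly ordered "
                f"rump < abdomen < chest < shoulder within [0, 1], got {fr}"
            )
        if self.mesh_resolution < 1:
            raise ValueError("mesh_resolution must be >= 1")

    # -- derived geometry ---------------------------------------------------

    def station_x(self, frac: float) -> float:
        """Map a body-length fraction to an x coordinate (tail -> head)."""
        return -self.torso_half_length + 2.0 * self.torso_half_length * frac

    @property
    def stations(self) -> dict[str, float]:
        return {
            "chest_station": self.station_x(self.chest_station_frac),
            "abdomen_station": self.station_x(self.abdomen_station_frac),
            "shoulder_plane": self.station_x(self.shoulder_plane_frac),
            "rump_plane": self.station_x(self.rump_plane_frac),
        }

    @property
    def effective_leg_length(self) -> float:
        """Leg length after the head-posture lever.

        A raised or lowered head shifts weight over the forelimbs and
        changes standing height slightly; modelled as a linear coupling
        between head pitch and effective leg length.
        """
        return self.leg_length + self.withers_lever * self.head_pitch

    def scaled(self, sx: float, sy: float | None = None, sz: float | None = None) -> "CowParams":
        """Anisotropically scaled copy (lengths x sx, widths x sy, heights x sz)."""
        sy = sx if sy is None else sy
        sz = sx if sz is None else sz
        return replace(
            self,
            torso_half_length=self.torso_half_length * sx,
            torso_half_width=self.torso_half_width * sy,
            torso_half_height=self.torso_half_height * sz,
            torso_center_height=self.torso_center_height * sz,
            leg_length=self.leg_length * sz,
            leg_radius=self.leg_radius * 0.5 * (sy + sz),
            head_length=self.head_length * sx,
            head_radius=self.head_radius * 0.5 * (sy + sz),
            withers_bump_height=self.withers_bump_height * sz,
            tail_radius=self.tail_radius * 0.5 * (sy + sz),
        )


def adult_cow_params(**overrides) -> CowParams:
    """Preset calibrated to the adult reference-cohort means
    (TV ~ 764 L, TS ~ 7.2 m^2, WH ~ 1.45 m)."""
    return CowParams(**overrides)


def heifer_params(**overrides) -> CowParams:
    """Adult preset scaled anisotropically to the heifer-cohort means
    (TV ~ 581 L, WH ~ 1.38 m, hip width ~ 0.51 m)."""
    base = adult_cow_params()
    sz = 1.376 / 1.454
    sy = 0.507 / 0.575
    sx = (581.2 / 763.9) / (sy * sz)
    return replace(base.scaled(sx, sy, sz), **overrides)


def ellipsoid_params(
    a: float = 1.0, b: float = 0.4, c: float = 0.45, resolution: int = 4
) -> CowParams:
    """Degenerate preset: a pure ellipsoid torso resting on the ground
    plane (legs, head and withers bump disabled) for closed-form checks."""
    return CowParams(
        torso_half_length=a,
        torso_half_width=b,
        torso_half_height=c,
        torso_shape_exponents=(1.0, 1.0),
        torso_center_height=c,
        n_legs=0,
        neck_head_enabled=False,
        withers_bump_height=0.0,
        tail_enabled=False,
        mesh_resolution=resolution,
    )


@dataclass(frozen=True)
class NoiseModel:
    """Layered measurement-noise model.

    ``click_jitter_sd`` perturbs landmark/station coordinates on every
    repeated identification (repeatability).  ``posture_pitch_sd`` /
    ``posture_shift_sd`` perturb head pitch and stance between
    acquisition sessions only (reproducibility), and
    ``surface_noise_sd`` displaces mesh vertices along their normals
    per session (acquisition/reconstruction noise).  Defaults are
    calibrated so simulated trait CVs land in the sub-4% range typical
    of one-shot depth-camera devices.
    """

    click_jitter_sd: float = 0.004
    posture_pitch_sd: float = 0.06
    posture_shift_sd: float = 0.012
    surface_noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("click_jitter_sd", "posture_pitch_sd", "posture_shift_sd", "surface_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """One of the validation study layouts.

    ``repeatability``: one acquisition per animal, landmark clicking
    repeated ``n_repeats`` times.  ``reproducibility``: ``n_sessions``
    acquisitions per animal (posture re-drawn each time), each clicked
    ``n_repeats`` times.
    """

    kind: str = "repeatability"
    n_subjects: int = 8
    n_sessions: int = 1
    n_repeats: int = 5
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.kind not in ("repeatability", "reproducibility", "comparison", "bw_cohort"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.kind == "repeatability" and self.n_sessions != 1:
            raise ValueError("repeatability design requires n_sessions = 1")
        if self.kind == "reproducibility" and self.n_sessions < 2:
            raise ValueError("reproducibility design requires n_sessions > 1")
        if min(self.n_subjects, self.n_sessions, self.n_repeats) < 1:
            raise ValueError("design counts must be >= 1")

    @property
    def n_records(self) -> int:
        return self.n_subjects * self.n_sessions * self.n_repeats


# ---------------------------------------------------------------------------
# implicit body


def _smin(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    """Polynomial smooth minimum with blend radius ``k``."""
    if k <= 0:
        return np.minimum(a, b)
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b + (a - b) * h - k * h * (1.0 - h)


def _capsule_sdf(p: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    pa = p - a
    ba = b - a
    h = np.clip((pa @ ba) / (ba @ ba), 0.0, 1.0)
    return np.linalg.norm(pa - h[:, None] * ba, axis=1) - r


class CowBody:
    """Implicit-surface body for a :class:`CowParams`.

    ``sdf`` is negative inside.  It is a true distance only near the
    capsule parts; for the superellipsoid it is a monotone level
    function, which marching cubes localises equally well.
    """

    blend = 0.06  # smooth-union radius, m

    def __init__(self, params: CowParams):
        self.p = params
        p = params
        self.z0 = p.effective_leg_length + (p.torso_center_height - p.leg_length)
        # leg anchor stations, inboard of the torso ends
        self.leg_x = [-0.62 * p.torso_half_length, 0.62 * p.torso_half_length]
        self.leg_y = 0.55 * p.torso_half_width
        if p.neck_head_enabled:
            d = np.array([math.cos(p.head_pitch), 0.0, math.sin(p.head_pitch)])
            self.head_a = np.array(
                [0.82 * p.torso_half_length, 0.0, self.z0 + 0.45 * p.torso_half_height]
            )
            self.head_b = self.head_a + p.head_length * d
        self.withers_x = p.station_x(p.shoulder_plane_frac * 0.97)

    def _torso(self, pts: np.ndarray) -> np.ndarray:
        p = self.p
        e_cross, e_prof = p.torso_shape_exponents
        x = pts[:, 0] / p.torso_half_length
        y = pts[:, 1] / p.torso_half_width
        z = (pts[:, 2] - self.z0) / p.torso_half_height
        m = np.maximum
        w = (
            m(np.abs(y), 1e-12) ** (2.0 / e_cross) + m(np.abs(z), 1e-12) ** (2.0 / e_cross)
        ) ** (e_cross / e_prof) + m(np.abs(x), 1e-12) ** (2.0 / e_prof)
        # pseudo-distance: scale the level value so its gradient is O(1)
        scale = min(p.torso_half_width, p.torso_half_height) / 2.0
        return (w ** (e_prof / 2.0) - 1.0) * scale

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        p = self.p
        pts = np.asarray(pts, dtype=float)
        f = self._torso(pts)
        if p.withers_bump_height > 0:
            bump_c = np.array([self.withers_x, 0.0, self.z0 + p.torso_half_height])
            rel = (pts - bump_c) / np.array(
                [0.30 * p.torso_half_length, 0.8 * p.torso_half_width, 2.2 * p.withers_bump_height]
            )
            bump = (np.linalg.norm(rel, axis=1) - 1.0) * p.withers_bump_height
            f = _smin(f, bump, self.blend)
        if p.n_legs > 0:
            leg_len = p.effective_leg_length
            r = p.leg_radius
            xs = self.leg_x[: max(1, p.n_legs // 2)]
            for lx in xs:
                # legs slant like a standing cow's: forelimbs forward,
                # hindlimbs backward, so shin sections are disjoint from
                # the attachment and a transverse plane through the
                # shins yields separate leg contours
                slant = math.copysign(0.13 * p.torso_half_length, lx)
                for ly in (-self.leg_y, self.leg_y):
                    a = np.array([lx + slant, ly, r])
                    b = np.array([lx, ly, max(2 * r, leg_len)])
                    f = _smin(f, _capsule_sdf(pts, a, b, r), self.blend)
        if p.neck_head_enabled:
            f = _smin(f, _capsule_sdf(pts, self.head_a, self.head_b, p.head_radius), self.blend)
        if p.tail_enabled:
            a = np.array([-0.985 * p.torso_half_length, 0.0, self.z0 + 0.45 * p.torso_half_height])
            b = np.array([-1.04 * p.torso_half_length, 0.0, 0.32 * self.z0])
            f = _smin(f, _capsule_sdf(pts, a, b, p.tail_radius), 0.5 * self.blend)
        return f

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.p
        margin = 3.0 * self.blend
        xmax = p.torso_half_length + margin
        zmax = self.z0 + p.torso_half_height + p.withers_bump_height + margin
        if p.neck_head_enabled:
            xmax = max(xmax, self.head_b[0] + p.head_radius + margin)
            zmax = max(zmax, self.head_b[2] + p.head_radius + margin)
        xlo = (1.06 if p.tail_enabled else 1.0) * p.torso_half_length
        if p.n_legs > 0:
            xlo = max(xlo, 0.75 * p.torso_half_length + p.leg_radius)
            xmax = max(xmax, 0.75 * p.torso_half_length + p.leg_radius + margin)
        lo = np.array([-xlo - margin, -p.torso_half_width - margin, -0.02])
        hi = np.array([xmax, p.torso_half_width + margin, zmax])
        return lo, hi

    def surface_point(self, origin, direction, t_max: float = 3.0) -> np.ndarray:
        """First outer sdf zero-crossing along ``origin + t*direction``."""
        direction = np.asarray(direction, float)
        direction = direction / np.linalg.norm(direction)
        origin = np.asarray(origin, float)
        ts = np.linspace(0.0, t_max, 400)
        vals = self.sdf(origin[None, :] + ts[:, None] * direction)
        sign = np.sign(vals)
        idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        if len(idx) == 0:
            raise ValueError("no surface crossing along the probe ray")
        i = idx[-1]  # outermost crossing: the surface seen from outside
        lo, hi = ts[i], ts[i + 1]
        flo = vals[i]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            fm = float(self.sdf((origin + mid * direction)[None, :])[0])
            if (fm < 0) == (flo < 0):
                lo, flo = mid, fm
            else:
                hi = mid
        return origin + 0.5 * (lo + hi) * direction


def _grid_for(body: CowBody, resolution: int) -> list[np.ndarray]:
    lo, hi = body.bounds()
    extent = hi - lo
    # voxel pitch halves with every two resolution steps
    pitch = 0.05 / (2 ** ((resolution - 1) / 2))
    ns = np.maximum((extent / pitch).astype(int) + 2, 24)
    return [np.linspace(lo[k], hi[k], ns[k]) for k in range(3)]


def make_cow_mesh(params: CowParams) -> trimesh.Trimesh:
    """Mesh the implicit body with marching cubes.

    Returns a watertight, consistently oriented mesh standing on the
    ground plane (minimum vertex height exactly 0), longitudinal axis
    on x with the head toward +x.  Raises
    :class:`~ruminant3d.morphometry.MeshDefectError` if the result is
    not watertight.
    """
    body = CowBody(params)
    axes = _grid_for(body, params.mesh_resolution)
    spacing = tuple(float(a[1] - a[0]) for a in axes)
    mesh = None
    # marching cubes can produce degenerate (non-manifold) junctions
    # when the surface grazes grid nodes; a sub-voxel shift of the
    # sampling lattice resolves them
    for shift_frac in (0.0, 0.31, 0.57):
        sa = [a + shift_frac * spacing[k] for k, a in enumerate(axes)]
        X, Y, Z = np.meshgrid(*sa, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        F = body.sdf(pts).reshape(X.shape)
        verts, faces, _, _ = sk_measure.marching_cubes(F, level=0.0, spacing=spacing)
        verts += np.array([sa[0][0], sa[1][0], sa[2][0]])
        candidate = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        if candidate.is_watertight:
            mesh = candidate
            break
    if mesh is None:
        raise morphometry.MeshDefectError(
            "marching-cubes body is not watertight at any lattice offset; "
            "the implicit surface probably crossed the sampling grid boundary"
        )
    if mesh.volume < 0:
        mesh.invert()
    # stand exactly on the ground plane
    mesh.apply_translation([0.0, 0.0, -mesh.bounds[0][2]])
    return mesh


# ---------------------------------------------------------------------------
# ground-truth landmarks and traits

# hip / pin-bone stations as body-length fractions: the hooks sit ahead
# of the pins, both on the rear quarter, at the lateral extremes of
# their transverse sections
_HIP_FRAC = 0.165
_PIN_FRAC = 0.135


def true_landmarks(params: CowParams, body: CowBody | None = None) -> FeaturePoints:
    """Noise-free landmark set evaluated on the implicit surface."""
    body = body or CowBody(params)
    p = params
    st = p.stations
    z0 = body.z0
    up = np.array([0.0, 0.0, 1.0])

    withers = body.surface_point(np.array([body.withers_x, 0.0, z0]), up)
    x_hip = p.station_x(_HIP_FRAC)
    x_pin = p.station_x(_PIN_FRAC)
    hips, pins = [], []
    for sgn in (1.0, -1.0):
        lateral = np.array([0.0, sgn, 0.0])  # widest point of the section
        hips.append(body.surface_point(np.array([x_hip, 0.0, z0]), lateral))
        pins.append(body.surface_point(np.array([x_pin, 0.0, z0]), lateral))
    tips_sh, tips_bt = [], []
    for sgn in (1.0, -1.0):
        d_fwd = np.array([math.cos(0.5), sgn * math.sin(0.5), 0.0])
        d_back = np.array([-math.cos(0.5), sgn * math.sin(0.5), 0.0])
        tips_sh.append(
            body.surface_point(np.array([st["shoulder_plane"] - 0.1, 0.0, z0]), d_fwd)
        )
        tips_bt.append(body.surface_point(np.array([st["rump_plane"], 0.0, z0]), d_back))

    return FeaturePoints(
        withers=withers,
        hip_left=hips[0],
        hip_right=hips[1],
        pin_left=pins[0],
        pin_right=pins[1],
        shoulder_tip_left=tips_sh[0],
        shoulder_tip_right=tips_sh[1],
        buttock_tip_left=tips_bt[0],
        buttock_tip_right=tips_bt[1],
        **st,
    )


def _ellipse_perimeter(b: float, c: float) -> float:
    """Ellipse perimeter from the complete elliptic integral E(m)."""
    from scipy.special import ellipe

    hi, lo = max(b, c), min(b, c)
    if hi == 0:
        return 0.0
    return float(4.0 * hi * ellipe(1.0 - (lo / hi) ** 2))


def _is_pure_ellipsoid(p: CowParams) -> bool:
    return (
        p.n_legs == 0
        and not p.neck_head_enabled
        and p.withers_bump_height == 0.0
        and tuple(p.torso_shape_exponents) == (1.0, 1.0)
    )


def true_traits(params: CowParams) -> TraitVector:
    """Ground-truth traits: closed-form where available, otherwise
    measured on a reference mesh at twice the working grid density."""
    ref = replace(params, mesh_resolution=params.mesh_resolution + 2)
    mesh = make_cow_mesh(ref)
    fp = true_landmarks(ref)
    t = morphometry.measure_all(mesh, fp)
    if _is_pure_ellipsoid(params):
        a, b, c = params.torso_half_length, params.torso_half_width, params.torso_half_height
        t.tv = 4.0 / 3.0 * math.pi * a * b * c
        u = params.stations["chest_station"] / a
        shrink = math.sqrt(max(0.0, 1.0 - u * u))
        t.cd = 2.0 * c * shrink
        t.hg = _ellipse_perimeter(b * shrink, c * shrink)
        ua = params.stations["abdomen_station"] / a
        sh = math.sqrt(max(0.0, 1.0 - ua * ua))
        t.ac = _ellipse_perimeter(b * sh, c * sh)
    return t


# ---------------------------------------------------------------------------
# study generation


@dataclass
class StudyRecord:
    """One measurement occasion: the session mesh plus one clicked
    (jittered) landmark set."""

    subject: int
    session: int
    repeat: int
    mesh: trimesh.Trimesh
    landmarks: FeaturePoints
    params: CowParams


def _jitter_landmarks(fp: FeaturePoints, sd: float, rng: np.random.Generator) -> FeaturePoints:
    out = {}
    for name in morphometry.LANDMARK_NAMES:
        v = getattr(fp, name)
        if v is not None:
            out[name] = v + rng.normal(0.0, sd, size=3)
    for name in morphometry.STATION_NAMES:
        s = getattr(fp, name)
        if s is not None:
            out[name] = float(s + rng.normal(0.0, sd))
    return FeaturePoints(**out)


def _session_variant(params: CowParams, noise: NoiseModel, rng: np.random.Generator) -> CowParams:
    return replace(
        params,
        head_pitch=params.head_pitch + rng.normal(0.0, noise.posture_pitch_sd),
        leg_length=max(0.3, params.leg_length + rng.normal(0.0, noise.posture_shift_sd)),
    )


def _roughen(mesh: trimesh.Trimesh, sd: float, rng: np.random.Generator) -> trimesh.Trimesh:
    if sd <= 0:
        return mesh
    out = mesh.copy()
    out.vertices = out.vertices + out.vertex_normals * rng.normal(
        0.0, sd, size=(len(out.vertices), 1)
    )
    return out


def generate_study(design: StudyDesign, base_params: Sequence[CowParams]) -> list[StudyRecord]:
    """Instantiate a study design over a list of subjects.

    Emits exactly ``n_subjects * n_sessions * n_repeats`` records.
    Within one (subject, session) pair the mesh object is shared and
    only the clicked landmarks differ; across sessions posture and
    surface noise are re-drawn.  Fully reproducible from the noise
    model's seed via counter-based seed splitting.
    """
    if len(base_params) != design.n_subjects:
        raise ValueError(f"need {design.n_subjects} parameter sets, got {len(base_params)}")
    noise = design.noise
    records: list[StudyRecord] = []
    for si, params in enumerate(base_params):
        for sess in range(design.n_sessions):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=(noise.seed, si, sess)))
            sp = _session_variant(params, noise, rng) if design.n_sessions > 1 else params
            mesh = _roughen(make_cow_mesh(sp), noise.surface_noise_sd, rng)
            fp = true_landmarks(sp)
            for rep in range(design.n_repeats):
                rr = np.random.default_rng(
                    np.random.SeedSequence(entropy=(noise.seed, si, sess, rep, 7))
                )
                lm = _jitter_landmarks(fp, noise.click_jitter_sd, rr)
                records.append(StudyRecord(si, sess, rep, mesh, lm, sp))
    assert len(records) == design.n_records
    return records


def measure_study(records: Sequence[StudyRecord], derive_totals: bool = True):
    """Measure every record into a long-format table.

    With ``derive_totals`` (the partial-image workflow), TV and TS are
    derived from PV and PS through the published conversion equations
    rather than read off the full mesh, so they inherit the
    landmark-identification variability like every clicked trait.

    Returns a pandas DataFrame with columns
    (subject, session, repeat, trait, value, unit).
    """
    import pandas as pd

    units = {
        "wh": "m", "hw": "m", "wb": "m", "cd": "m", "hg": "m", "ac": "m",
        "dl": "m", "ps": "m2", "ts": "m2", "pv": "m3", "tv": "m3",
    }
    rows = []
    for rec in records:
        t = morphometry.measure_all(rec.mesh, rec.landmarks)
        if derive_totals and not (math.isnan(t.pv) or math.isnan(t.ps)):
            t.tv = prediction.total_volume_from_partial(t.pv)
            t.ts = prediction.total_surface_from_partial(t.ps)
        for k, v in t.as_dict().items():
            if not math.isnan(v):
                rows.append(
                    dict(
                        subject=rec.subject,
                        session=rec.session,
                        repeat=rec.repeat,
                        trait=k,
                        value=v,
                        unit=units[k],
                    )
                )
    return pd.DataFrame(rows)


def scale_weight(traits: TraitVector, residual_sd: float = 0.0, seed: int | None = None) -> float:
    """Simulated weigh-scale reading for an animal with the given traits.

    The reading is the published prediction-equation weight plus a
    Gaussian residual; ``residual_sd = 0`` returns the equation value
    exactly.
    """
    if residual_sd < 0:
        raise ValueError("residual_sd must be >= 0")
    bw = prediction.predict_bw(traits.tv, traits.hw, traits.wb)
    if residual_sd > 0:
        rng = np.random.default_rng(seed)
        bw += float(rng.normal(0.0, residual_sd))
    return bw


def make_herd(
    n: int,
    base: CowParams | None = None,
    size_cv: float = 0.035,
    seed: int = 0,
) -> list[CowParams]:
    """A herd of ``n`` animals: the base preset under mild independent
    anisotropic size variation (default 3.5% SD per axis group)."""
    base = base or adult_cow_params()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 1234)))
    herd = []
    for i in range(n):
        sx, sy, sz = rng.normal(1.0, size_cv, size=3)
        herd.append(replace(base.scaled(sx, sy, sz), seed=seed + i))
    return herd
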