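"""Ground-truthed synthetic fixtures: parametric radius-like meshes,
malunion deformation, truth plans, simulated surgery and scan noise.

The radius surrogate is a parametric swept surface — elliptical
cross-sections with a distal flare and a slanted distal rim whose radial
prominence stands in for the styloid.  Every landmark and every stored
transform is analytic, so the ground truth against which the measurement
pipeline is checked is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PlanningError
from .frame import AxisLine, LandmarkSet, build_frame, world_alignment
from .geometry import (
    Plane,
    RigidTransform,
    TriangleMesh,
    cut_with_plane,
    mirror,
    mirror_transform,
)
from .measurement import ClinicalErrorDecomposition, compose_errors
from .planning import OsteotomyPlan

__all__ = [
    "RadiusParams",
    "MalunionSpec",
    "ResidualErrorSpec",
    "SyntheticCase",
    "generate_radius",
    "induce_malunion",
    "default_osteotomy_plane",
    "truth_plan",
    "simulate_surgery",
    "simulate_scan",
    "generate_study",
    "sample_case_errors",
    "default_arm_specs",
    "cylinder_mesh",
]

_FOLD = np.sqrt(2.0 / np.pi)  # E|N(0,1)|


# ---------------------------------------------------------------------------
# generic fixture helpers
# ---------------------------------------------------------------------------


def cylinder_mesh(
    radius: float = 10.0,
    length: float = 70.0,
    n_theta: int = 48,
    n_z: int = 40,
    closed: bool = True,
    z_top: float = 0.0,
) -> TriangleMesh:
    """Closed circular cylinder along z with top face at ``z_top``."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(z_top - length, z_top, n_z + 1)
    rings = np.array(
        [[(radius * np.cos(t), radius * np.sin(t), zz) for t in theta] for zz in z]
    ).reshape(-1, 3)
    verts = [rings]
    faces = []
    for j in range(n_z):
        for i in range(n_theta):
            a = j * n_theta + i
            b = j * n_theta + (i + 1) % n_theta
            c = a + n_theta
            d = b + n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    if closed:
        bot = len(rings)
        top = bot + 1
        verts.append(np.array([[0.0, 0.0, z_top - length], [0.0, 0.0, z_top]]))
        for i in range(n_theta):
            faces.append([bot, (i + 1) % n_theta, i])
            faces.append([top, n_z * n_theta + i, n_z * n_theta + (i + 1) % n_theta])
    return TriangleMesh(np.vstack(verts), np.asarray(faces))


# ---------------------------------------------------------------------------
# parametric radius
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadiusParams:
    """Parameters of the radius surrogate.

    The distal rim is slanted: its most distal point (the styloid analogue)
    sits on the radial (+x) side, ``styloid_height`` mm beyond the ulnar
    rim.  ``shaft_bow_deg`` is the maximum tangent angle of the bowed
    centerline.  ``n_theta`` must be a multiple of 4 so the analytic
    landmark positions fall exactly on mesh vertices at any density.
    """

    shaft_length: float = 90.0
    a_proximal: float = 7.0
    b_proximal: float = 6.0
    a_distal: float = 5.5
    b_distal: float = 4.5
    flare_a: float = 6.0
    flare_b: float = 3.0
    flare_start: float = 0.75  # fraction of length where the flare begins
    styloid_height: float = 6.0
    shaft_bow_deg: float = 3.0
    crest_amp: float = 0.10  # 3rd-harmonic cross-section term (interosseous crest)
    wave_amp: float = 0.04  # longitudinal girth undulation (fades distally)
    wave_freq: float = 3.0
    n_theta: int = 48
    n_z: int = 120
    side: str = "right"
    seed: int = 0

    def __post_init__(self):
        positive = [
            self.shaft_length,
            self.a_proximal,
            self.b_proximal,
            self.a_distal,
            self.b_distal,
            self.styloid_height,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all dimensions must be positive")
        if self.flare_a < 0 or self.flare_b < 0:
            raise ValueError("flare widths must be non-negative")
        if not 0 < self.flare_start < 1:
            raise ValueError("flare_start must be in (0, 1)")
        if not 0 <= self.crest_amp <= 0.3:
            raise ValueError("crest_amp must be in [0, 0.3]")
        if self.n_theta < 8 or self.n_theta % 4:
            raise ValueError("n_theta must be a multiple of 4, >= 8")
        if self.n_z < 10:
            raise ValueError("n_z must be >= 10")
        if self.shaft_length < 60:
            raise ValueError("shaft must be >= 60 mm for the axis segment to fit")


def _radius_profiles(p: RadiusParams):
    """Analytic cross-section functions of the normalized coordinate u."""

    def flare(u):
        t = np.clip((u - p.flare_start) / (1 - p.flare_start), 0.0, None)
        return t**2

    def wave(u):
        # girth undulation along the shaft: pins down axial translation in
        # registration (a constant-profile tube would leave it free); the
        # (1 - u) factor makes it vanish at the rim so landmark formulas
        # are unaffected.  Centroids stay on the centerline (isotropic in
        # the section plane), so the analytic truth axis is unaffected too.
        u = np.asarray(u)
        return 1.0 + p.wave_amp * np.sin(2 * np.pi * p.wave_freq * u) * (1.0 - u)

    def ax(u):
        return (
            p.a_proximal + (p.a_distal - p.a_proximal) * u + p.flare_a * flare(u)
        ) * wave(u)

    def ay(u):
        return (
            p.b_proximal + (p.b_distal - p.b_proximal) * u + p.flare_b * flare(u)
        ) * wave(u)

    bow_amp = np.tan(np.radians(p.shaft_bow_deg)) * p.shaft_length / 2.0

    def cx(u):
        return bow_amp * np.asarray(u) ** 2

    def z_rim(theta):
        return p.shaft_length + p.styloid_height * (1 + np.cos(theta)) / 2.0

    def slant(u):
        # rim slant confined to the flare region: shaft cross-sections stay
        # planar rings, so constant-depth sections match the analytic
        # centerline exactly on the axis-fit segment
        t = np.clip(
            (np.asarray(u) - p.flare_start) / (1 - p.flare_start), 0.0, None
        )
        return t**2

    def crest(theta):
        # 3rd harmonic: breaks axial rotation symmetry (a surface of
        # revolution would leave ICP's axial mode unconstrained) without
        # shifting ring centroids, so the analytic centerline stays exact
        return 1.0 + p.crest_amp * np.cos(3.0 * np.asarray(theta))

    return ax, ay, cx, z_rim, crest, slant


def generate_radius(
    params: RadiusParams = RadiusParams(),
) -> tuple[TriangleMesh, LandmarkSet, AxisLine]:
    """Generate a radius surrogate with analytic landmarks and truth axis.

    Landmarks (exact mesh vertices for any tessellation density):

    * CRP: distal rim at theta = pi (ulnar side, sigmoid-notch analogue),
    * styloid tip: distal rim at theta = 0,
    * volar reference: distal rim at theta = pi/2 (+y).

    The returned axis line is the least-squares line through the analytic
    ring centroids of the 30-50 mm segment proximal of the CRP.
    """
    p = params
    ax, ay, cx, z_rim, crest, slant = _radius_profiles(p)
    theta = 2 * np.pi * np.arange(p.n_theta) / p.n_theta
    u = np.linspace(0.0, 1.0, p.n_z + 1)

    uu, tt = np.meshgrid(u, theta, indexing="ij")
    x = cx(uu) + ax(uu) * crest(tt) * np.cos(tt)
    y = ay(uu) * crest(tt) * np.sin(tt)
    z = uu * p.shaft_length + slant(uu) * p.styloid_height * (1 + np.cos(tt)) / 2.0
    rings = np.stack([x, y, z], axis=-1).reshape(-1, 3)

    n_t = p.n_theta
    faces = []
    for j in range(p.n_z):
        base = j * n_t
        nxt = base + n_t
        for i in range(n_t):
            i2 = (i + 1) % n_t
            faces.append([base + i, base + i2, nxt + i2])
            faces.append([base + i, nxt + i2, nxt + i])
    # caps: proximal fan + distal articular fan
    prox_apex = np.array([cx(0.0), 0.0, 0.0])
    dist_apex = np.array([cx(1.0), 0.0, p.shaft_length + p.styloid_height / 2.0])
    n_rings = (p.n_z + 1) * n_t
    bot, top = n_rings, n_rings + 1
    last = p.n_z * n_t
    for i in range(n_t):
        i2 = (i + 1) % n_t
        faces.append([bot, i2, i])
        faces.append([top, last + i, last + i2])
    verts = np.vstack([rings, prox_apex[None], dist_apex[None]])
    mesh = TriangleMesh(verts, np.asarray(faces))

    crp = np.array([cx(1.0) - ax(1.0) * (1 - p.crest_amp), 0.0, z_rim(np.pi)])
    styloid = np.array([cx(1.0) + ax(1.0) * (1 + p.crest_amp), 0.0, z_rim(0.0)])
    volar = np.array([cx(1.0), ay(1.0), z_rim(np.pi / 2)])
    landmarks = LandmarkSet(crp=crp, styloid_tip=styloid, volar_ref=volar, side="right")

    axis = _truth_axis(p)

    if p.side == "left":
        m = Plane(np.zeros(3), np.array([1.0, 0.0, 0.0]))
        t = mirror_transform(m)
        mesh = mirror(mesh, m)
        landmarks = LandmarkSet(
            crp=t.apply(landmarks.crp),
            styloid_tip=t.apply(landmarks.styloid_tip),
            volar_ref=t.apply(landmarks.volar_ref),
            side="left",
        )
        axis = AxisLine(t.apply(axis.point), t.rotation @ axis.direction)
    return mesh, landmarks, axis


def _truth_axis(p: RadiusParams) -> AxisLine:
    """Least-squares line through analytic ring centroids, 30-50 mm
    proximal of the CRP (measured along z)."""
    _, _, cx, _, _, slant = _radius_profiles(p)
    z_crp = p.shaft_length  # rim height at theta = pi
    u = np.linspace(0.0, 1.0, 2001)
    zc = u * p.shaft_length + slant(u) * p.styloid_height / 2.0
    depth = z_crp - zc
    sel = (depth >= 30.0) & (depth <= 50.0)
    pts = np.stack([cx(u[sel]), np.zeros(sel.sum()), zc[sel]], axis=1)
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    d = vt[0]
    if d[2] < 0:
        d = -d
    return AxisLine(c, d)


# ---------------------------------------------------------------------------
# malunion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MalunionSpec:
    """Deformity applied to the distal fragment, in frame-axis terms."""

    plane: Plane
    dorsal_tilt_deg: float = 20.0
    radial_inclination_loss_deg: float = 5.0
    shortening_mm: float = 3.0
    axial_rotation_deg: float = 0.0

    def __post_init__(self):
        if abs(self.dorsal_tilt_deg) > 40:
            raise ValueError("dorsal tilt beyond clinically plausible 40 deg")
        if abs(self.shortening_mm) > 10:
            raise ValueError("shortening beyond clinically plausible 10 mm")


def default_osteotomy_plane(frame_origin, z_axis, offset_mm: float = 20.0) -> Plane:
    """Transverse plane ``offset_mm`` proximal of the CRP, normal distal."""
    origin = np.asarray(frame_origin, dtype=np.float64)
    z = np.asarray(z_axis, dtype=np.float64)
    return Plane(origin - offset_mm * z, z)


def induce_malunion(
    healthy: TriangleMesh, landmarks: LandmarkSet, spec: MalunionSpec
) -> tuple[TriangleMesh, LandmarkSet, RigidTransform]:
    """Displace the distal fragment into a malunited pose.

    The transform is composed from rotations about the anatomical frame
    axes at the osteotomy-plane reference point (dorsal tilt = negative
    volar rotation), followed by shortening along -z.  The junction is left
    as an open step; the transform is returned as ground truth.
    """
    frame = build_frame(healthy, landmarks)
    b = frame.basis  # frame axes as columns
    local = compose_errors(
        ClinicalErrorDecomposition(
            rot_x_deg=-spec.dorsal_tilt_deg,
            rot_y_deg=-spec.radial_inclination_loss_deg,
            rot_z_deg=spec.axial_rotation_deg,
            trans_x_mm=0.0,
            trans_y_mm=0.0,
            trans_z_mm=0.0,
        )
    ).rotation
    r_world = b @ local @ b.T
    rot = RigidTransform.from_rotation_about(r_world, spec.plane.point)
    shift = RigidTransform.from_translation(-spec.shortening_mm * frame.z_axis)
    transform = shift.compose(rot)

    distal, proximal = cut_with_plane(healthy, spec.plane)
    if distal.is_empty() or proximal.is_empty():
        raise PlanningError("malunion plane does not separate a distal fragment")
    malunited = TriangleMesh.concatenate(proximal, distal.transformed(transform))
    return malunited, landmarks.transformed(transform), transform


def truth_plan(
    healthy: TriangleMesh,
    malunited: TriangleMesh,
    malunion_transform: RigidTransform,
    plane: Plane,
) -> OsteotomyPlan:
    """Exact plan whose correction is the inverse of the known malunion."""
    correction = malunion_transform.invert()
    distal, proximal = cut_with_plane(malunited, plane)
    if distal.is_empty() or proximal.is_empty():
        raise PlanningError("plane does not separate the malunited mesh")
    return OsteotomyPlan(
        osteotomy_plane=plane,
        proximal_part=proximal,
        distal_part_corrected=distal.transformed(correction),
        correction=correction,
        reference_residual=0.0,
    )


# ---------------------------------------------------------------------------
# simulated surgery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidualErrorSpec:
    """Scales of the signed residual errors a guide arm leaves behind.

    ``rot_scales`` / ``trans_scales`` are SDs of centred normal draws for
    (x, y, z) rotations [deg] and translations [mm]; the absolute values of
    such draws follow the folded normal with mean ``scale * sqrt(2/pi)``.
    """

    rot_scales: tuple = (1.0, 1.0, 1.0)
    trans_scales: tuple = (0.5, 0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        if any(s < 0 for s in (*self.rot_scales, *self.trans_scales)):
            raise ValueError("scales must be >= 0")


def default_arm_specs() -> dict[str, ResidualErrorSpec]:
    """Default per-arm residual scales.

    Chosen so the folded means emulate the absolute-error magnitudes
    reported for in-house versus externally designed guides in clinical
    accuracy studies of this workflow (a few degrees / about a millimetre).
    """
    return {
        "in_house": ResidualErrorSpec(
            rot_scales=(2.61 / _FOLD, 1.96 / _FOLD, 3.39 / _FOLD),
            trans_scales=(0.90 / _FOLD, 0.98 / _FOLD, 0.90 / _FOLD),
        ),
        "external": ResidualErrorSpec(
            rot_scales=(4.93 / _FOLD, 3.13 / _FOLD, 3.96 / _FOLD),
            trans_scales=(1.28 / _FOLD, 1.08 / _FOLD, 1.29 / _FOLD),
        ),
    }


def sample_case_errors(
    spec: ResidualErrorSpec, rng: np.random.Generator
) -> ClinicalErrorDecomposition:
    r = rng.normal(0.0, spec.rot_scales)
    t = rng.normal(0.0, spec.trans_scales)
    return ClinicalErrorDecomposition(
        rot_x_deg=float(r[0]),
        rot_y_deg=float(r[1]),
        rot_z_deg=float(r[2]),
        trans_x_mm=float(t[0]),
        trans_y_mm=float(t[1]),
        trans_z_mm=float(t[2]),
    )


def simulate_surgery(
    plan: OsteotomyPlan,
    landmarks: LandmarkSet,
    injected: ClinicalErrorDecomposition,
) -> TriangleMesh:
    """Build the surgical-result mesh for a given injected residual error.

    The planned correction is perturbed by the residual transform composed
    from the injected parameters in anatomical-frame coordinates at the
    frame origin, exactly the space in which the measurement pipeline will
    read the error back.
    """
    planned_full = TriangleMesh.concatenate(plan.proximal_part, plan.distal_part_corrected)
    frame = build_frame(planned_full, landmarks)
    w = world_alignment(frame)
    perturb_world = w.invert().compose(compose_errors(injected)).compose(w)
    return TriangleMesh.concatenate(
        plan.proximal_part, plan.distal_part_corrected.transformed(perturb_world)
    )


def simulate_scan(mesh: TriangleMesh, sigma_mm: float, seed: int = 0) -> TriangleMesh:
    """Optical-scan emulation: Gaussian vertex noise along vertex normals.

    ``sigma_mm = 0`` returns the input mesh unchanged; the default scanner
    noise scale elsewhere in the package is 0.05 mm (single-shot error of
    the reference scanner class).
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_mm == 0:
        return mesh
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, sigma_mm, mesh.n_vertices)
    return TriangleMesh(
        mesh.vertices + offsets[:, None] * mesh.vertex_normals(), mesh.faces.copy()
    )


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCase:
    """Complete ground-truth record of one synthetic patient case."""

    case_id: str
    seed: int
    params: RadiusParams
    malunion_spec: MalunionSpec
    healthy_mesh: TriangleMesh
    healthy_mirrored_mesh: TriangleMesh
    landmarks: LandmarkSet
    malunited_mesh: TriangleMesh
    malunited_landmarks: LandmarkSet
    malunion_transform: RigidTransform
    truth_axis: AxisLine
    plan: OsteotomyPlan
    result_meshes: dict = field(default_factory=dict)
    injected_errors: dict = field(default_factory=dict)


def _sample_uniform(rng, lo, hi):
    return float(lo + (hi - lo) * rng.random())


def generate_case(
    case_id: str,
    seed: int,
    arm_specs: dict[str, ResidualErrorSpec] | None = None,
    radius_ranges: dict | None = None,
    malunion_ranges: dict | None = None,
    noise_sigma: float = 0.0,
) -> SyntheticCase:
    """Generate one fully ground-truthed case (both guide arms)."""
    rng = np.random.default_rng(seed)
    rr = radius_ranges or {}
    mr = malunion_ranges or {}
    params = RadiusParams(
        shaft_length=_sample_uniform(rng, *rr.get("shaft_length", (85.0, 95.0))),
        a_proximal=_sample_uniform(rng, *rr.get("a_proximal", (6.5, 7.5))),
        b_proximal=_sample_uniform(rng, *rr.get("b_proximal", (5.5, 6.5))),
        shaft_bow_deg=_sample_uniform(rng, *rr.get("shaft_bow_deg", (1.0, 5.0))),
        styloid_height=_sample_uniform(rng, *rr.get("styloid_height", (5.0, 7.0))),
        seed=seed,
    )
    healthy, landmarks, axis = generate_radius(params)
    # the mirrored healthy contralateral mirrored back onto the injured side:
    # mirror is an exact involution, so this reproduces the healthy geometry
    sagittal = Plane(np.zeros(3), np.array([1.0, 0.0, 0.0]))
    healthy_mirrored = mirror(mirror(healthy, sagittal), sagittal)

    frame = build_frame(healthy, landmarks)
    plane = default_osteotomy_plane(frame.origin, frame.z_axis, 20.0)
    spec = MalunionSpec(
        plane=plane,
        dorsal_tilt_deg=_sample_uniform(rng, *mr.get("dorsal_tilt_deg", (10.0, 30.0))),
        radial_inclination_loss_deg=_sample_uniform(
            rng, *mr.get("radial_inclination_loss_deg", (0.0, 10.0))
        ),
        shortening_mm=_sample_uniform(rng, *mr.get("shortening_mm", (1.0, 5.0))),
        axial_rotation_deg=_sample_uniform(rng, *mr.get("axial_rotation_deg", (-5.0, 5.0))),
    )
    malunited, mal_landmarks, mal_transform = induce_malunion(healthy, landmarks, spec)
    plan = truth_plan(healthy, malunited, mal_transform, plane)

    case = SyntheticCase(
        case_id=case_id,
        seed=seed,
        params=params,
        malunion_spec=spec,
        healthy_mesh=healthy,
        healthy_mirrored_mesh=healthy_mirrored,
        landmarks=landmarks,
        malunited_mesh=malunited,
        malunited_landmarks=mal_landmarks,
        malunion_transform=mal_transform,
        truth_axis=axis,
        plan=plan,
    )
    for arm, spec_arm in (arm_specs or default_arm_specs()).items():
        arm_key = int.from_bytes(arm.encode("utf-8"), "little") % 2**31
        arm_rng = np.random.default_rng([seed, spec_arm.seed, arm_key])
        injected = sample_case_errors(spec_arm, arm_rng)
        result = simulate_surgery(plan, landmarks, injected)
        if noise_sigma > 0:
            result = simulate_scan(result, noise_sigma, seed=int(arm_rng.integers(2**31)))
        case.result_meshes[arm] = result
        case.injected_errors[arm] = injected
    return case


def generate_study(
    n_cases: int = 16,
    seed: int = 0,
    arm_specs: dict[str, ResidualErrorSpec] | None = None,
    radius_ranges: dict | None = None,
    malunion_ranges: dict | None = None,
    noise_sigma: float = 0.0,
) -> tuple[list[SyntheticCase], pd.DataFrame]:
    """Generate a reproducible study cohort and its injected-truth table.

    The returned data frame has one row per case per arm with the injected
    (signed) error parameters and feeds ``stats.study_table`` directly.
    """
    root = np.random.default_rng(seed)
    case_seeds = root.integers(0, 2**31, size=n_cases)
    cases, rows = [], []
    for i, cs in enumerate(case_seeds):
        case = generate_case(
            case_id=f"case_{i + 1:02d}",
            seed=int(cs),
            arm_specs=arm_specs,
            radius_ranges=radius_ranges,
            malunion_ranges=malunion_ranges,
            noise_sigma=noise_sigma,
        )
        cases.append(case)
        for arm, injected in case.injected_errors.items():
            rows.append(
                {
                    "case_id": case.case_id,
                    "guide_arm": arm,
                    "rot_x": injected.rot_x_deg,
                    "rot_y": injected.rot_y_deg,
                    "rot_z": injected.rot_z_deg,
                    "trans_x": injected.trans_x_mm,
                    "trans_y": injected.trans_y_mm,
                    "trans_z": injected.trans_z_mm,
                }
            )
    return cases, pd.DataFrame(rows)
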