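"""Correction-error measurement: Cardan decomposition and the two-stage
registration pipeline.

Rotation convention (a recorded dialect, switchable only here):

* factorisation ``R = Rz(gamma) @ Ry(beta) @ Rx(alpha)`` — extrinsic
  x -> y -> z Cardan sequence, so the x angle (the primary clinical
  endpoint, volar tilt) is read directly;
* the x rotation generator is oriented so that a rotation carrying the
  distal direction (+z) toward the volar direction (+y) is *positive*:
  volar tilt positive, dorsal tilt negative;
* y and z rotations follow the right-hand rule about their axes;
* translations are read directly, +z = lengthening.

The measurement pipeline mirrors the clinical procedure: register the
surgical result to the planned model on the proximal shaft, express both in
the anatomical frame, register distally, and decompose the residual distal
transform into the six clinical parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GimbalLockError, RegistrationError, TransformValidationError
from .frame import LandmarkSet, build_frame, world_alignment
from .geometry import Plane, RigidTransform, TriangleMesh
from .registration import IcpParams, icp, restrict_to_region, sample_surface

__all__ = [
    "ClinicalErrorDecomposition",
    "MeasurementResult",
    "GIMBAL_GUARD_DEG",
    "rot_x_volar",
    "rot_y",
    "rot_z",
    "compose_errors",
    "decompose",
    "measure_errors",
]

GIMBAL_GUARD_DEG = 60.0


def rot_x_volar(angle_deg: float) -> np.ndarray:
    """Rotation about x with volar-positive sign (+z tips toward +y)."""
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])


def rot_y(angle_deg: float) -> np.ndarray:
    """Right-hand rotation about y."""
    b = math.radians(angle_deg)
    c, s = math.cos(b), math.sin(b)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(angle_deg: float) -> np.ndarray:
    """Right-hand rotation about z."""
    g = math.radians(angle_deg)
    c, s = math.cos(g), math.sin(g)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class ClinicalErrorDecomposition:
    """Six correction-error parameters.

    rot_x_deg: volar tilt error (volar positive);
    rot_y_deg: radial inclination error;
    rot_z_deg: axial rotation error;
    trans_z_mm: radial length / ulnar variance error (lengthening positive).
    """

    rot_x_deg: float
    rot_y_deg: float
    rot_z_deg: float
    trans_x_mm: float
    trans_y_mm: float
    trans_z_mm: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.rot_x_deg,
                self.rot_y_deg,
                self.rot_z_deg,
                self.trans_x_mm,
                self.trans_y_mm,
                self.trans_z_mm,
            ]
        )

    def to_dict(self) -> dict:
        return {
            "rot_x_deg": self.rot_x_deg,
            "rot_y_deg": self.rot_y_deg,
            "rot_z_deg": self.rot_z_deg,
            "trans_x_mm": self.trans_x_mm,
            "trans_y_mm": self.trans_y_mm,
            "trans_z_mm": self.trans_z_mm,
        }


def compose_errors(dec: ClinicalErrorDecomposition) -> RigidTransform:
    """Rebuild the rigid transform from six clinical parameters."""
    r = rot_z(dec.rot_z_deg) @ rot_y(dec.rot_y_deg) @ rot_x_volar(dec.rot_x_deg)
    t = np.array([dec.trans_x_mm, dec.trans_y_mm, dec.trans_z_mm])
    return RigidTransform(r, t)


def decompose(transform: RigidTransform) -> ClinicalErrorDecomposition:
    """Factor a proper rigid transform into the six clinical parameters.

    Raises :class:`GimbalLockError` when |rot_y| exceeds the 60 deg guard
    (clinical corrections are far smaller).
    """
    if not transform.proper:
        raise TransformValidationError(
            "decompose requires a proper transform; conjugate improper maps "
            "into the frame first"
        )
    r = transform.rotation
    sb = float(np.clip(-r[2, 0], -1.0, 1.0))
    beta = math.asin(sb)
    if abs(math.degrees(beta)) >= GIMBAL_GUARD_DEG:
        raise GimbalLockError(
            f"|rot_y| = {abs(math.degrees(beta)):.1f} deg exceeds the "
            f"{GIMBAL_GUARD_DEG} deg gimbal guard"
        )
    alpha_std = math.atan2(r[2, 1], r[2, 2])
    gamma = math.atan2(r[1, 0], r[0, 0])
    t = transform.translation
    return ClinicalErrorDecomposition(
        rot_x_deg=-math.degrees(alpha_std),  # volar-positive dialect
        rot_y_deg=math.degrees(beta),
        rot_z_deg=math.degrees(gamma),
        trans_x_mm=float(t[0]),
        trans_y_mm=float(t[1]),
        trans_z_mm=float(t[2]),
    )


@dataclass
class MeasurementResult:
    """Output of :func:`measure_errors` with per-stage diagnostics."""

    errors: ClinicalErrorDecomposition
    proximal_residual: float
    distal_residual: float
    proximal_transform: RigidTransform
    distal_transform: RigidTransform
    frame_handedness: str


def measure_errors(
    result_mesh: TriangleMesh,
    plan,
    landmarks: LandmarkSet,
    params: IcpParams = IcpParams(),
    region_margin: float = 2.0,
    proximal_margin: float = 5.0,
) -> MeasurementResult:
    """Measure the six correction errors of a surgical result against a plan.

    Pipeline:

    1. coarse whole-surface ICP, then proximal-region ICP of the result onto
       the planned proximal part (absorbs any common rigid motion of the
       result mesh);
    2. anatomical frame built on the planned model; both models aligned to
       the world coordinate system (improper map for left-handed frames);
    3. distal-region ICP of the result onto the planned distal part,
       initialised at identity;
    4. Cardan decomposition of the *inverse* of the stage-3 transform, i.e.
       of the map carrying the planned distal fragment onto the achieved
       one, expressed in frame coordinates.

    The two region stages always run with the automatic distance threshold:
    residual errors push distal-fragment points across the osteotomy plane,
    and the trimming keeps those strays out of the proximal estimate.  The
    proximal dead zone is wider (``proximal_margin``) for the same reason.
    """
    plane: Plane = plan.osteotomy_plane
    planned_full = TriangleMesh.concatenate(plan.proximal_part, plan.distal_part_corrected)
    stage_params = IcpParams(
        max_iterations=params.max_iterations,
        convergence_tol=params.convergence_tol,
        sample_count=params.sample_count,
        trim_mode="auto_threshold",
        metric="point_to_plane",
        seed=params.seed,
    )

    # stage 1a: coarse co-registration of the whole result
    coarse_params = IcpParams(
        max_iterations=min(30, params.max_iterations),
        convergence_tol=params.convergence_tol,
        sample_count=params.sample_count,
        trim_mode="auto_threshold",
        metric="point_to_plane",
        seed=params.seed,
    )
    try:
        coarse = icp(result_mesh, planned_full, None, coarse_params)
    except RegistrationError as exc:
        raise RegistrationError(str(exc), stage="coarse") from exc

    # stage 1b: proximal-only refinement
    pts = sample_surface(result_mesh, params.sample_count * 2, params.seed)
    prox_mask = plane.signed_distance(coarse.transform.apply(pts)) < -proximal_margin
    if prox_mask.sum() < 3:
        raise RegistrationError("no proximal points after coarse alignment", stage="proximal")
    try:
        prox_res = icp(pts[prox_mask], plan.proximal_part, coarse.transform, stage_params)
    except RegistrationError as exc:
        raise RegistrationError(str(exc), stage="proximal") from exc
    t_prox = prox_res.transform

    # stage 2: anatomical frame on the planned model, world alignment
    frame = build_frame(planned_full, landmarks)
    w = world_alignment(frame)

    # stage 3: distal ICP in world (= frame) coordinates
    result_aligned = w.compose(t_prox)
    dist_mask = plane.signed_distance(t_prox.apply(pts)) > region_margin
    if dist_mask.sum() < 3:
        raise RegistrationError("no distal points after proximal alignment", stage="distal")
    moving_pts = result_aligned.apply(pts[dist_mask])
    fixed_distal = plan.distal_part_corrected.transformed(w)
    try:
        dist_res = icp(moving_pts, fixed_distal, None, stage_params)
    except RegistrationError as exc:
        raise RegistrationError(str(exc), stage="distal") from exc

    # stage 4: plan -> result map in frame coordinates
    errors = decompose(dist_res.transform.invert())
    return MeasurementResult(
        errors=errors,
        proximal_residual=prox_res.mean_residual,
        distal_residual=dist_res.mean_residual,
        proximal_transform=t_prox,
        distal_transform=dist_res.transform,
        frame_handedness=frame.handedness,
    )
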