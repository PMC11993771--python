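"""Virtual osteotomy planning.

The planned correction is obtained by cutting the malunited radius at the
osteotomy plane and rigidly aligning the distal fragment onto the distal
region of the mirrored healthy reference (assumed already registered to the
malunited proximal shaft by a prior ICP call).  Drill trajectories designed
in the corrected pose are carried back to the malunited pose by the inverse
correction, which is how guide drill holes end up at the right place on the
uncorrected bone.

Plates, screw sleeves and guide bodies are deliberately represented only as
abstract drill trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import PlanningError, RegistrationError
from .geometry import Plane, RigidTransform, TriangleMesh, cut_with_plane, read_stl, write_stl
from .registration import IcpParams, icp

__all__ = [
    "OsteotomyPlan",
    "DrillTrajectory",
    "plan_correction",
    "back_transform_drills",
    "save_plan",
    "load_plan",
]


@dataclass(frozen=True)
class DrillTrajectory:
    """Abstract drill hole: entry point, unit direction, length, diameter."""

    entry: np.ndarray
    direction: np.ndarray
    length: float
    diameter: float

    def __post_init__(self):
        e = np.ascontiguousarray(self.entry, dtype=np.float64).reshape(3)
        d = np.ascontiguousarray(self.direction, dtype=np.float64).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("drill direction must be nonzero")
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("drill length and diameter must be positive")
        object.__setattr__(self, "entry", e)
        object.__setattr__(self, "direction", d / n)

    def transformed(self, transform: RigidTransform) -> "DrillTrajectory":
        return DrillTrajectory(
            entry=transform.apply(self.entry),
            direction=transform.rotation @ self.direction,
            length=self.length,
            diameter=self.diameter,
        )

    def to_dict(self) -> dict:
        return {
            "entry": self.entry.tolist(),
            "direction": self.direction.tolist(),
            "length": self.length,
            "diameter": self.diameter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DrillTrajectory":
        return cls(
            np.asarray(d["entry"]),
            np.asarray(d["direction"]),
            d["length"],
            d["diameter"],
        )


@dataclass
class OsteotomyPlan:
    """Planned correction of one case.

    ``correction`` maps the distal fragment from its malunited pose to the
    corrected pose; ``distal_part_corrected`` is exactly the cut distal
    fragment under that transform.  The osteotomy plane normal points
    distally by package convention.
    """

    osteotomy_plane: Plane
    proximal_part: TriangleMesh
    distal_part_corrected: TriangleMesh
    correction: RigidTransform
    reference_residual: float

    def __post_init__(self):
        if not self.correction.proper:
            raise PlanningError("correction must be a proper rigid transform")


def plan_correction(
    malunited: TriangleMesh,
    healthy_mirrored: TriangleMesh,
    plane: Plane,
    params: IcpParams = IcpParams(),
    init: RigidTransform | None = None,
) -> OsteotomyPlan:
    """Plan the osteotomy correction against a mirrored healthy reference.

    The distal side of ``plane`` is its positive side (normal points
    distally).  ``init`` seeds the fragment ICP; identity is adequate for
    the deformity magnitudes this workflow targets.
    """
    distal, proximal = cut_with_plane(malunited, plane)
    if distal.is_empty() or proximal.is_empty():
        raise PlanningError("osteotomy plane does not separate a distal fragment")
    # the fragment alignment always runs point-to-plane with the automatic
    # distance threshold: the fragment's cut boundary has no counterpart on
    # the healthy reference and must not drag the estimate
    frag_params = IcpParams(
        max_iterations=max(params.max_iterations, 100),
        convergence_tol=params.convergence_tol,
        sample_count=params.sample_count,
        trim_mode="auto_threshold",
        metric="point_to_plane",
        seed=params.seed,
    )
    try:
        result = icp(distal, healthy_mirrored, init, frag_params)
    except RegistrationError as exc:
        raise PlanningError(f"fragment registration failed: {exc}") from exc
    correction = result.transform
    return OsteotomyPlan(
        osteotomy_plane=plane,
        proximal_part=proximal,
        distal_part_corrected=distal.transformed(correction),
        correction=correction,
        reference_residual=result.mean_residual,
    )


def back_transform_drills(
    plan: OsteotomyPlan, drills_in_corrected_pose: list[DrillTrajectory]
) -> list[DrillTrajectory]:
    """Carry drill trajectories from the corrected pose back to the
    malunited pose (inverse of the planned correction)."""
    inv = plan.correction.invert()
    return [d.transformed(inv) for d in drills_in_corrected_pose]


def save_plan(plan: OsteotomyPlan, json_path, stl_prefix=None) -> None:
    """Serialise a plan: JSON with the correction + plane, STL part files."""
    json_path = str(json_path)
    prefix = str(stl_prefix) if stl_prefix is not None else json_path[: -len(".json")]
    prox_path = prefix + "_proximal.stl"
    dist_path = prefix + "_distal_corrected.stl"
    write_stl(plan.proximal_part, prox_path)
    write_stl(plan.distal_part_corrected, dist_path)
    payload = {
        "correction": plan.correction.matrix.tolist(),
        "reference_residual": plan.reference_residual,
        "osteotomy_plane": {
            "point": plan.osteotomy_plane.point.tolist(),
            "normal": plan.osteotomy_plane.normal.tolist(),
        },
        "proximal_stl": prox_path,
        "distal_corrected_stl": dist_path,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_plan(json_path) -> OsteotomyPlan:
    with open(json_path) as fh:
        d = json.load(fh)
    return OsteotomyPlan(
        osteotomy_plane=Plane(
            np.asarray(d["osteotomy_plane"]["point"]),
            np.asarray(d["osteotomy_plane"]["normal"]),
        ),
        proximal_part=read_stl(d["proximal_stl"]),
        distal_part_corrected=read_stl(d["distal_corrected_stl"]),
        correction=RigidTransform.from_matrix(np.asarray(d["correction"])),
        reference_residual=d["reference_residual"],
    )
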