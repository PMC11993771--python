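"""Shared fixtures.

Heavy fixtures (the default synthetic radius and a complete synthetic case)
are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from radioplan.frame import LandmarkSet
from radioplan.geometry import Plane, RigidTransform
from radioplan.synthetic import RadiusParams, cylinder_mesh, generate_case, generate_radius


@pytest.fixture(scope="session")
def default_radius():
    """(mesh, landmarks, truth_axis) of the default parametric radius."""
    return generate_radius(RadiusParams())


@pytest.fixture(scope="session")
def default_case():
    """Complete noiseless synthetic case with both guide arms."""
    return generate_case("case_fix", seed=11)


@pytest.fixture()
def cylinder():
    """Closed cylinder along z, radius 10, z in [-70, 0]."""
    return cylinder_mesh(radius=10.0, length=70.0, z_top=0.0)


@pytest.fixture()
def cylinder_landmarks():
    return LandmarkSet(
        crp=np.array([0.0, 0.0, 0.0]),
        styloid_tip=np.array([10.0, 0.0, -2.0]),
        volar_ref=np.array([0.0, 5.0, -10.0]),
        side="right",
    )


def random_rigid_transform(rng: np.random.Generator, max_angle_deg=180.0, max_trans=50.0):
    """Uniformly random proper rigid transform (helper, not a fixture)."""
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(max_angle_deg) * (2 * rng.random() - 1)
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    return RigidTransform(rot, max_trans * (2 * rng.random(3) - 1))


@pytest.fixture()
def transverse_plane():
    return Plane(np.array([0.0, 0.0, 0.5]), np.array([0.0, 0.0, 1.0]))
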