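"""synthetic_anatomy: generator determinism, malunion truth, scan noise."""

import hashlib

import numpy as np
import pytest

from radioplan.frame import build_frame, central_axis, world_alignment
from radioplan.geometry import write_stl
from radioplan.measurement import ClinicalErrorDecomposition, decompose
from radioplan.synthetic import (
    MalunionSpec,
    RadiusParams,
    ResidualErrorSpec,
    default_arm_specs,
    default_osteotomy_plane,
    generate_case,
    generate_radius,
    generate_study,
    induce_malunion,
    sample_case_errors,
    simulate_scan,
    simulate_surgery,
)


def stl_digest(mesh, tmp_path, name):
    path = tmp_path / name
    write_stl(mesh, path, "binary")
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TestGenerateRadius:
    def test_deterministic(self, tmp_path):
        m1, lm1, ax1 = generate_radius(RadiusParams())
        m2, lm2, ax2 = generate_radius(RadiusParams())
        assert stl_digest(m1, tmp_path, "a.stl") == stl_digest(m2, tmp_path, "b.stl")
        np.testing.assert_array_equal(lm1.crp, lm2.crp)

    def test_landmarks_independent_of_density(self):
        _, lm1, ax1 = generate_radius(RadiusParams(n_theta=32, n_z=60))
        _, lm2, ax2 = generate_radius(RadiusParams(n_theta=64, n_z=240))
        np.testing.assert_array_equal(lm1.crp, lm2.crp)
        np.testing.assert_array_equal(lm1.styloid_tip, lm2.styloid_tip)
        np.testing.assert_array_equal(lm1.volar_ref, lm2.volar_ref)
        np.testing.assert_allclose(ax1.direction, ax2.direction, atol=1e-12)

    def test_no_bow_axis_is_z(self):
        mesh, lm, truth = generate_radius(RadiusParams(shaft_bow_deg=0.0))
        np.testing.assert_allclose(truth.direction, [0, 0, 1], atol=1e-9)
        fitted = central_axis(mesh, lm.crp)
        cos = abs(np.dot(fitted.direction, truth.direction))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 0.1

    def test_left_side_mirrored(self):
        right, lm_r, _ = generate_radius(RadiusParams())
        left, lm_l, _ = generate_radius(RadiusParams(side="left"))
        np.testing.assert_allclose(lm_l.crp, lm_r.crp * [-1, 1, 1], atol=1e-12)
        f = build_frame(left, lm_l)
        assert f.handedness == "left"

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RadiusParams(shaft_length=-1.0)
        with pytest.raises(ValueError):
            RadiusParams(n_theta=30)  # not a multiple of 4
        with pytest.raises(ValueError):
            RadiusParams(shaft_length=40.0)  # too short for axis segment

    def test_mesh_valid_and_frame_constructible_over_ranges(self):
        for bow in (0.0, 5.0):
            for styloid in (4.0, 8.0):
                mesh, lm, _ = generate_radius(
                    RadiusParams(shaft_bow_deg=bow, styloid_height=styloid)
                )
                assert np.isfinite(mesh.vertices).all()
                f = build_frame(mesh, lm)
                assert f.handedness == "right"


class TestInduceMalunion:
    def test_zero_spec_is_identity(self, default_radius):
        mesh, lm, _ = default_radius
        frame = build_frame(mesh, lm)
        plane = default_osteotomy_plane(frame.origin, frame.z_axis, 20.0)
        spec = MalunionSpec(plane, 0.0, 0.0, 0.0, 0.0)
        mal, mal_lm, t = induce_malunion(mesh, lm, spec)
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-12
        assert np.abs(t.translation).max() < 1e-12
        # geometry unchanged up to the cut-and-merge bookkeeping
        assert mal.area() == pytest.approx(mesh.area(), rel=1e-6)

    def test_dorsal_tilt_sign(self, default_radius):
        # dorsal tilt = negative volar rotation in frame coordinates
        mesh, lm, _ = default_radius
        frame = build_frame(mesh, lm)
        plane = default_osteotomy_plane(frame.origin, frame.z_axis, 20.0)
        spec = MalunionSpec(plane, dorsal_tilt_deg=20.0, radial_inclination_loss_deg=0.0,
                            shortening_mm=0.0, axial_rotation_deg=0.0)
        _, _, t = induce_malunion(mesh, lm, spec)
        w = world_alignment(frame)
        t_frame = w.compose(t).compose(w.invert())
        d = decompose(t_frame)
        assert d.rot_x_deg == pytest.approx(-20.0, abs=1e-9)

    def test_random_spec_decomposes_to_spec_values(self, default_radius):
        mesh, lm, _ = default_radius
        frame = build_frame(mesh, lm)
        plane = default_osteotomy_plane(frame.origin, frame.z_axis, 20.0)
        rng = np.random.default_rng(8)
        for _ in range(5):
            spec = MalunionSpec(
                plane,
                dorsal_tilt_deg=float(rng.uniform(-30, 30)),
                radial_inclination_loss_deg=float(rng.uniform(-10, 10)),
                shortening_mm=float(rng.uniform(0, 5)),
                axial_rotation_deg=float(rng.uniform(-10, 10)),
            )
            _, _, t = induce_malunion(mesh, lm, spec)
            w = world_alignment(frame)
            d = decompose(w.compose(t).compose(w.invert()))
            assert d.rot_x_deg == pytest.approx(-spec.dorsal_tilt_deg, abs=1e-9)
            assert d.rot_y_deg == pytest.approx(
                -spec.radial_inclination_loss_deg, abs=1e-9
            )
            assert d.rot_z_deg == pytest.approx(spec.axial_rotation_deg, abs=1e-9)

    def test_implausible_specs_rejected(self, transverse_plane):
        with pytest.raises(ValueError):
            MalunionSpec(transverse_plane, dorsal_tilt_deg=50.0)
        with pytest.raises(ValueError):
            MalunionSpec(transverse_plane, shortening_mm=15.0)


class TestSimulateSurgery:
    def test_zero_errors_reproduce_plan(self, default_case):
        case = default_case
        zero = ClinicalErrorDecomposition(0, 0, 0, 0, 0, 0)
        result = simulate_surgery(case.plan, case.landmarks, zero)
        planned = np.vstack(
            [case.plan.proximal_part.vertices, case.plan.distal_part_corrected.vertices]
        )
        np.testing.assert_allclose(result.vertices, planned, atol=1e-9)

    def test_deterministic_sampling(self):
        spec = ResidualErrorSpec(rot_scales=(2, 2, 2), trans_scales=(1, 1, 1))
        a = sample_case_errors(spec, np.random.default_rng(5)).as_array()
        b = sample_case_errors(spec, np.random.default_rng(5)).as_array()
        np.testing.assert_array_equal(a, b)

    def test_zero_scale_spec_gives_zero_errors(self):
        spec = ResidualErrorSpec(rot_scales=(0, 0, 0), trans_scales=(0, 0, 0))
        e = sample_case_errors(spec, np.random.default_rng(1))
        np.testing.assert_array_equal(e.as_array(), np.zeros(6))


class TestSimulateScan:
    def test_sigma_zero_identity(self, default_radius):
        mesh = default_radius[0]
        out = simulate_scan(mesh, 0.0, seed=3)
        assert out is mesh

    def test_folded_mean_displacement(self, default_radius):
        mesh = default_radius[0]
        disp = []
        for seed in range(10):
            noisy = simulate_scan(mesh, 0.05, seed=seed)
            disp.append(np.linalg.norm(noisy.vertices - mesh.vertices, axis=1).mean())
        assert np.mean(disp) == pytest.approx(0.05 * np.sqrt(2 / np.pi), rel=0.05)

    def test_different_seeds_differ(self, default_radius):
        mesh = default_radius[0]
        a = simulate_scan(mesh, 0.05, seed=1)
        b = simulate_scan(mesh, 0.05, seed=2)
        assert a.n_vertices == b.n_vertices == mesh.n_vertices
        assert not np.array_equal(a.vertices, b.vertices)

    def test_negative_sigma_rejected(self, default_radius):
        with pytest.raises(ValueError):
            simulate_scan(default_radius[0], -0.1)


class TestGenerateStudy:
    def test_stored_transforms_reproduce_meshes(self):
        case = generate_case("c", seed=5)
        # correction applied to the cut distal fragment equals the stored
        # corrected part (the SyntheticCase core invariant)
        from radioplan.geometry import cut_with_plane

        distal, _ = cut_with_plane(case.malunited_mesh, case.plan.osteotomy_plane)
        np.testing.assert_allclose(
            case.plan.correction.apply(distal.vertices),
            case.plan.distal_part_corrected.vertices,
            atol=1e-9,
        )
        assert case.plan.correction.almost_equal(
            case.malunion_transform.invert(), atol=1e-9
        )

    def test_csv_reproducible(self, tmp_path):
        _, df1 = generate_study(n_cases=3, seed=12)
        _, df2 = generate_study(n_cases=3, seed=12)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        df1.to_csv(p1, index=False)
        df2.to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_csv_feeds_study_table(self):
        from radioplan.stats import study_table

        _, df = generate_study(n_cases=4, seed=2)
        summary, decisions = study_table(df)
        assert set(decisions) == {"rot_x", "trans_z"}

    def test_arm_specs_respected(self):
        zero = ResidualErrorSpec(rot_scales=(0, 0, 0), trans_scales=(0, 0, 0))
        _, df = generate_study(n_cases=2, seed=1, arm_specs={"in_house": zero, "external": zero})
        vals = df[["rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z"]].to_numpy()
        np.testing.assert_array_equal(vals, np.zeros_like(vals))

    def test_default_arm_specs_magnitudes(self):
        specs = default_arm_specs()
        # external arm is the noisier one on every rotation scale
        assert all(
            e > i
            for e, i in zip(specs["external"].rot_scales, specs["in_house"].rot_scales)
        )
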