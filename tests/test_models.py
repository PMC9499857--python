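"""Forward generative models: bilinear face, linear eyelid, sphere eyeball,
rigid pose and camera projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocumask import (
    Camera,
    EyeballModel,
    EyeballRotation,
    EyelidModel,
    EyelidParams,
    FaceParams,
    ParametricFaceModel,
    RigidPose,
    apply_pose,
    eyeball_mesh,
    eyeball_rotation_matrix,
    project,
    reconstruct_face,
    reconstruct_eyelid,
)
from ocumask.errors import (
    ContractViolationError,
    DegenerateProjectionError,
    DimensionMismatchError,
)


def random_face_model(rng, n_v=4, n_s=2, n_m=3):
    core = rng.standard_normal((3 * n_v, n_s, n_m))
    return ParametricFaceModel(core, np.array([[0, 1, 2]]))


class TestBilinearFace:
    def test_single_slice_identity(self, rng):
        core = rng.standard_normal((12, 1, 1))
        model = ParametricFaceModel(core, np.array([[0, 1, 2]]))
        out = reconstruct_face(model, FaceParams([1.0], [1.0]))
        np.testing.assert_array_equal(out.ravel(), core[:, 0, 0])

    def test_matches_triple_loop_oracle(self, rng):
        model = random_face_model(rng)
        ws, wm = rng.standard_normal(2), rng.standard_normal(3)
        out = reconstruct_face(model, FaceParams(ws, wm))
        oracle = np.zeros(12)
        for s in range(2):
            for m in range(3):
                oracle += model.core_tensor[:, s, m] * ws[s] * wm[m]
        np.testing.assert_allclose(out.ravel(), oracle, atol=1e-12)

    def test_bilinear_homogeneity(self, rng):
        model = random_face_model(rng)
        ws, wm = rng.standard_normal(2), rng.standard_normal(3)
        base = reconstruct_face(model, FaceParams(ws, wm))
        doubled = reconstruct_face(model, FaceParams(2 * ws, wm))
        np.testing.assert_allclose(doubled, 2 * base, rtol=1e-12)

    def test_dimension_mismatch_names_axis(self, rng):
        model = random_face_model(rng)
        with pytest.raises(DimensionMismatchError, match="shape axis"):
            reconstruct_face(model, FaceParams([1.0], np.zeros(3)))
        with pytest.raises(DimensionMismatchError, match="motion axis"):
            reconstruct_face(model, FaceParams(np.zeros(2), [1.0]))


class TestLinearEyelid:
    def _model(self, rng, n_v=5, n_s=2, n_m=3):
        return EyelidModel(
            rng.standard_normal(3 * n_v),
            rng.standard_normal((n_s, 3 * n_v)),
            rng.standard_normal((n_m, 3 * n_v)),
        )

    def test_zero_weights_return_template(self, rng):
        model = self._model(rng)
        out = reconstruct_eyelid(model, EyelidParams(np.zeros(2), np.zeros(3)))
        np.testing.assert_array_equal(out.ravel(), model.template)

    def test_matches_component_sum_oracle(self, rng):
        model = self._model(rng)
        ws, wm = rng.standard_normal(2), rng.standard_normal(3)
        out = reconstruct_eyelid(model, EyelidParams(ws, wm))
        oracle = model.template.copy()
        for i in range(2):
            oracle = oracle + ws[i] * model.shape_basis[i]
        for j in range(3):
            oracle = oracle + wm[j] * model.motion_basis[j]
        np.testing.assert_allclose(out.ravel(), oracle, atol=1e-12)

    def test_affine_superposition(self, rng):
        model = self._model(rng)
        w1 = (rng.standard_normal(2), rng.standard_normal(3))
        w2 = (rng.standard_normal(2), rng.standard_normal(3))
        lhs = reconstruct_eyelid(
            model, EyelidParams(w1[0] + w2[0], w1[1] + w2[1])
        )
        rhs = (
            reconstruct_eyelid(model, EyelidParams(*w1))
            + reconstruct_eyelid(model, EyelidParams(*w2))
            - model.template.reshape(-1, 3)
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestEyeballSphere:
    def test_all_vertices_on_sphere(self):
        mesh = eyeball_mesh(EyeballModel(12.0, 6.0))
        np.testing.assert_allclose(
            np.linalg.norm(mesh.vertices, axis=1), 12.0, atol=1e-9
        )

    def test_iris_ring_polar_angle(self):
        # r_e=12, r_i=6: the ring sits at arcsin(0.5) = 30 deg from the gaze axis
        mesh = eyeball_mesh(EyeballModel(12.0, 6.0))
        ring = mesh.vertices[mesh.iris_ring]
        gaze = np.array([0.0, 0.0, -1.0])
        angles = np.arccos(ring @ gaze / 12.0)
        np.testing.assert_allclose(angles, np.arcsin(0.5), atol=1e-12)
        # and the ring has the planar radius r_i
        np.testing.assert_allclose(np.hypot(ring[:, 0], ring[:, 1]), 6.0, atol=1e-9)

    def test_homogeneous_scaling(self):
        m1 = eyeball_mesh(EyeballModel(8.0, 4.0))
        m2 = eyeball_mesh(EyeballModel(16.0, 8.0))
        np.testing.assert_allclose(m2.vertices, 2 * m1.vertices, atol=1e-9)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ContractViolationError):
            EyeballModel(6.0, 6.0)


class TestRigidPose:
    def test_identity(self, rng):
        pts = rng.standard_normal((10, 3))
        np.testing.assert_array_equal(apply_pose(pts, RigidPose.identity()), pts)

    def test_inverse_round_trip(self, rng):
        from scipy.spatial.transform import Rotation

        pose = RigidPose(Rotation.random(rng=1).as_matrix(), rng.standard_normal(3))
        pts = rng.standard_normal((10, 3))
        back = apply_pose(apply_pose(pts, pose), pose.inverse())
        np.testing.assert_allclose(back, pts, atol=1e-12)

    def test_composition_matches_matrix_oracle(self, rng):
        from scipy.spatial.transform import Rotation

        p1 = RigidPose(Rotation.random(rng=2).as_matrix(), rng.standard_normal(3))
        p2 = RigidPose(Rotation.random(rng=3).as_matrix(), rng.standard_normal(3))
        pts = rng.standard_normal((7, 3))
        lhs = apply_pose(apply_pose(pts, p2), p1)
        rhs = apply_pose(pts, p1.compose(p2))
        # oracle: homogeneous 4x4 product
        T1, T2 = np.eye(4), np.eye(4)
        T1[:3, :3], T1[:3, 3] = p1.rotation, p1.translation
        T2[:3, :3], T2[:3, 3] = p2.rotation, p2.translation
        hom = (np.column_stack([pts, np.ones(7)]) @ (T1 @ T2).T)[:, :3]
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)
        np.testing.assert_allclose(lhs, hom, atol=1e-10)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ContractViolationError):
            RigidPose(np.eye(3) * 1.1, np.zeros(3))

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rigid_motion_preserves_pairwise_distances(self, seed):
        from scipy.spatial.transform import Rotation

        r = np.random.default_rng(seed)
        pose = RigidPose(Rotation.random(rng=seed).as_matrix(), r.normal(size=3))
        pts = r.normal(size=(6, 3))
        moved = apply_pose(pts, pose)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestEyeballRotation:
    def test_zero_angles_identity(self):
        np.testing.assert_allclose(
            eyeball_rotation_matrix(EyeballRotation(0.0, 0.0)), np.eye(3), atol=1e-15
        )

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_orthonormal(self, theta, phi):
        R = eyeball_rotation_matrix(EyeballRotation(theta, phi))
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_quarter_pitch_matches_elementary_oracle(self):
        R = eyeball_rotation_matrix(EyeballRotation(np.pi / 2, 0.0))
        oracle = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        np.testing.assert_allclose(R, oracle, atol=1e-12)
        # gaze axis (0,0,-1) pitches onto +y
        np.testing.assert_allclose(R @ [0, 0, -1], [0, 1, 0], atol=1e-12)

    def test_yaw_applied_before_pitch(self):
        th, ph = 0.3, -0.7
        R = eyeball_rotation_matrix(EyeballRotation(th, ph))
        Rx = eyeball_rotation_matrix(EyeballRotation(th, 0.0))
        Ry = eyeball_rotation_matrix(EyeballRotation(0.0, ph))
        np.testing.assert_allclose(R, Rx @ Ry, atol=1e-12)


class TestProjection:
    def test_optical_axis_maps_to_principal_point(self):
        cam = Camera("pinhole", focal=1000.0, principal=(320.0, 240.0))
        np.testing.assert_allclose(project([[0, 0, 5.0]], cam), [[320, 240]])

    def test_pinhole_hand_case(self):
        # f*x/z + cx = 1000*0.1/2 + 320 = 370; 1000*(-0.2)/2 + 240 = 140
        cam = Camera("pinhole", focal=1000.0, principal=(320.0, 240.0))
        np.testing.assert_allclose(
            project([[0.1, -0.2, 2.0]], cam), [[370.0, 140.0]], atol=1e-12
        )

    def test_nonpositive_depth_lists_offenders(self):
        cam = Camera("pinhole")
        with pytest.raises(DegenerateProjectionError) as exc:
            project([[0, 0, 1.0], [0, 0, -1.0], [1, 1, 0.0]], cam)
        assert exc.value.indices == [1, 2]

    def test_weak_perspective_is_small_depth_limit_of_pinhole(self):
        square = np.array([[x, y, 0.0] for x in (-1, 1) for y in (-1, 1)])
        errs = []
        for z in (10.0, 100.0, 1000.0):
            pin = Camera("pinhole", focal=1000.0, principal=(0.0, 0.0))
            weak = Camera("weak_perspective", scale=1000.0 / z, principal=(0.0, 0.0))
            flat = square + [0, 0, z]
            errs.append(
                np.abs(project(flat, pin) - project(square, weak)).max()
            )
        assert errs == [0.0] * 3  # flat square: exact agreement at any depth
        # with depth variation the discrepancy vanishes as depth grows
        bumpy = square + [[0, 0, 0.1], [0, 0, -0.1], [0, 0, 0.05], [0, 0, -0.05]]
        errs = []
        for z in (10.0, 100.0, 1000.0):
            pin = Camera("pinhole", focal=1000.0, principal=(0.0, 0.0))
            weak = Camera("weak_perspective", scale=1000.0 / z, principal=(0.0, 0.0))
            errs.append(np.abs(project(bumpy + [0, 0, z], pin) - project(bumpy[:, :3] * [1, 1, 0], weak)).max())
        assert errs[0] > errs[1] > errs[2]

    def test_projection_commutes_with_vertex_reordering(self, rng):
        cam = Camera()
        pts = rng.normal(size=(20, 3)) + [0, 0, 50]
        perm = rng.permutation(20)
        np.testing.assert_array_equal(project(pts, cam)[perm], project(pts[perm], cam))
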