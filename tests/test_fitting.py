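"""Stage energies, analytic Jacobians, first-frame estimation and tracking."""

import numpy as np
import pytest

from ocumask import (
    Camera,
    EyeballRotation,
    FaceParams,
    ParametricFaceModel,
    RigidPose,
    SmoothingConfig,
    SolverConfig,
    face_energy,
    fit_circle_kasa,
    estimate_eyeball_statics,
    fit_eyeball_frame,
    fit_eyelid_first_frame,
    fit_face_first_frame,
    fit_face_frame,
    reconstruct_face,
)
from ocumask.errors import ContractViolationError, InsufficientDataError
from ocumask.features import LandmarkSet2D
from ocumask.fitting import (
    _eyeball_residual_builder,
    _eyelid_residual_builder,
    _face_residual_builder,
    build_dense_landmarks,
    semantic_line_energy,
)
from ocumask.liegroup import exp_so3
from ocumask.models import EyeballModel, apply_pose, eyeball_mesh
from ocumask.pipeline import project_state
from ocumask.solver import numerical_jacobian
from ocumask.synthetic import TrajectorySpec, generate_sequence

TIGHT = SolverConfig(max_iter=200)


# ---------------------------------------------------------------------------
# face energy


class TestFaceEnergy:
    def test_self_consistent_state_has_zero_energy(self, assets, camera, sweep_sequence):
        truth = sweep_sequence.truth[0]
        obs = sweep_sequence.observations[0]
        e, r = face_energy(
            assets.face_model, truth.face, truth.pose, camera, assets.cmap, obs.face
        )
        assert e == pytest.approx(0.0, abs=1e-16)

    def test_three_four_five_offset(self, assets, camera, sweep_sequence):
        truth = sweep_sequence.truth[0]
        obs = sweep_sequence.observations[0]
        pts = obs.face.points.copy()
        pts[4] += [3.0, 4.0]
        lm = LandmarkSet2D("face", pts)
        e, _ = face_energy(
            assets.face_model, truth.face, truth.pose, camera, assets.cmap, lm
        )
        assert e == pytest.approx(25.0, abs=1e-9)

    def test_matches_per_landmark_summation_oracle(self, assets, camera,
                                                   sweep_sequence, rng):
        truth = sweep_sequence.truth[0]
        obs = sweep_sequence.observations[0]
        pts = obs.face.points + rng.normal(0, 2, size=obs.face.points.shape)
        lm = LandmarkSet2D("face", pts)
        e, _ = face_energy(
            assets.face_model, truth.face, truth.pose, camera, assets.cmap, lm
        )
        M = reconstruct_face(assets.face_model, truth.face)
        oracle = 0.0
        for i, vi in enumerate(assets.cmap.face):
            v = truth.pose.rotation @ M[vi] + truth.pose.translation
            p = camera.project(v[None])[0]
            oracle += np.sum((pts[i] - p) ** 2)
        assert e == pytest.approx(oracle, rel=1e-12)

    def test_occluded_landmarks_contribute_nothing(self, assets, camera,
                                                   sweep_sequence):
        truth = sweep_sequence.truth[0]
        obs = sweep_sequence.observations[0]
        pts = obs.face.points.copy()
        pts[7] += [100.0, -50.0]
        vis = np.ones(len(pts), bool)
        vis[7] = False
        lm = LandmarkSet2D("face", pts, vis)
        e, r = face_energy(
            assets.face_model, truth.face, truth.pose, camera, assets.cmap, lm
        )
        assert e == pytest.approx(0.0, abs=1e-16)
        assert len(r) == 2 * (len(pts) - 1)

    def test_all_occluded_rejected(self, assets, camera, sweep_sequence):
        truth = sweep_sequence.truth[0]
        obs = sweep_sequence.observations[0]
        lm = LandmarkSet2D("face", obs.face.points,
                           np.zeros(len(obs.face.points), bool))
        with pytest.raises(InsufficientDataError):
            face_energy(assets.face_model, truth.face, truth.pose, camera,
                        assets.cmap, lm)


# ---------------------------------------------------------------------------
# analytic Jacobians vs central differences


class TestAnalyticJacobians:
    def test_face_jacobian_matches_finite_differences(self, assets, camera,
                                                      sweep_sequence, rng):
        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        R_ref = exp_so3(rng.normal(0, 0.05, 3))
        fn, _ = _face_residual_builder(
            assets.face_model, camera, assets.cmap, obs.face, R_ref, True,
            truth.face.shape,
        )
        n = (assets.face_model.n_shape - 1) + (assets.face_model.n_motion - 1) + 6
        x = np.concatenate([
            rng.normal(0, 0.3, assets.face_model.n_shape - 1),
            rng.normal(0, 0.3, assets.face_model.n_motion - 1),
            rng.normal(0, 0.05, 3),
            truth.pose.translation + rng.normal(0, 2, 3),
        ])
        assert x.shape[0] == n
        J = fn(x)[1]
        J_fd = numerical_jacobian(fn, x, step=1e-6)
        np.testing.assert_allclose(J, J_fd, rtol=1e-5, atol=1e-5)

    def test_face_tracking_jacobian_with_smoothing(self, assets, camera,
                                                   sweep_sequence, rng):
        obs = sweep_sequence.observations[1]
        truth = sweep_sequence.truth[0]
        prev = {"wm": truth.face.motion, "R": truth.pose.rotation,
                "t": truth.pose.translation}
        fn, _ = _face_residual_builder(
            assets.face_model, camera, assets.cmap, obs.face,
            truth.pose.rotation, False, truth.face.shape,
            prev=prev, smoothing=SmoothingConfig(),
        )
        x = np.concatenate([
            truth.face.motion[1:] + rng.normal(0, 0.1, 2),
            rng.normal(0, 0.03, 3),
            truth.pose.translation + rng.normal(0, 1, 3),
        ])
        np.testing.assert_allclose(
            fn(x)[1], numerical_jacobian(fn, x), rtol=1e-5, atol=1e-5
        )

    def test_eyelid_jacobian_matches_finite_differences(self, assets, camera,
                                                        sweep_sequence, rng):
        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        dense = build_dense_landmarks(obs, "left", assets.cmap)
        fn, _ = _eyelid_residual_builder(
            assets.eyelid_models["left"], camera, assets.cmap, "left", dense,
            obs.semantic_lines["left"], truth.pose, True,
            np.zeros(assets.eyelid_models["left"].n_shape),
        )
        x = rng.normal(0, 0.3, assets.eyelid_models["left"].n_shape
                       + assets.eyelid_models["left"].n_motion)
        np.testing.assert_allclose(
            fn(x)[1], numerical_jacobian(fn, x), rtol=1e-5, atol=1e-5
        )

    def test_eyeball_jacobian_matches_finite_differences(self, assets, camera,
                                                         sweep_sequence, rng):
        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        st = truth.statics["left"]
        ball = eyeball_mesh(EyeballModel(st.r_e, st.r_i)).vertices
        lm = obs.iris["left"]
        fn = _eyeball_residual_builder(
            ball, assets.cmap.iris["left"], lm.visibility, lm.points, st.p_e,
            truth.pose, camera, prev_angles=(0.01, -0.02),
            smoothing=SmoothingConfig(),
        )
        x = rng.normal(0, 0.2, 2)
        np.testing.assert_allclose(
            fn(x)[1], numerical_jacobian(fn, x), rtol=1e-5, atol=1e-6
        )


# ---------------------------------------------------------------------------
# face fitting


class TestFaceFitting:
    def test_zero_noise_recovery_from_perturbed_truth(self, assets, camera,
                                                      sweep_sequence, rng):
        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        init_params = FaceParams(
            truth.face.shape + rng.normal(0, 1e-3, truth.face.shape.shape),
            truth.face.motion + rng.normal(0, 1e-3, truth.face.motion.shape),
        )
        init_params.shape[0] = init_params.motion[0] = 1.0
        init_pose = RigidPose(
            exp_so3(rng.normal(0, 1e-3, 3)) @ truth.pose.rotation,
            truth.pose.translation + rng.normal(0, 1e-3, 3),
        )
        params, pose, sf = fit_face_first_frame(
            obs, assets.face_model, camera, assets.cmap, TIGHT,
            init_params=init_params, init_pose=init_pose,
        )
        err = np.concatenate([
            params.shape - truth.face.shape,
            params.motion - truth.face.motion,
            (pose.rotation - truth.pose.rotation).ravel(),
            (pose.translation - truth.pose.translation) / 100.0,
        ])
        assert np.sqrt(np.mean(err**2)) < 1e-6

    def test_zero_noise_recovery_from_generic_initialization(self, assets, camera,
                                                             sweep_sequence):
        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        params, pose, _ = fit_face_first_frame(
            obs, assets.face_model, camera, assets.cmap, TIGHT
        )
        np.testing.assert_allclose(params.shape, truth.face.shape, atol=1e-6)
        np.testing.assert_allclose(pose.translation, truth.pose.translation,
                                   atol=1e-4)

    def test_noisy_fit_matches_reference_least_squares(self, assets, camera,
                                                       sweep_sequence, rng):
        from scipy.optimize import least_squares

        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        for _ in range(3):
            pts = obs.face.points + rng.normal(0, 0.5, obs.face.points.shape)
            lm = LandmarkSet2D("face", pts)
            fn, unpack = _face_residual_builder(
                assets.face_model, camera, assets.cmap, lm,
                truth.pose.rotation, True, truth.face.shape,
            )
            x0 = np.concatenate([
                truth.face.shape[1:], truth.face.motion[1:], np.zeros(3),
                truth.pose.translation,
            ])
            x_gn, rep = gauss_newton_wrap(fn, x0)
            ref = least_squares(lambda x: fn(x)[0], x0, jac=lambda x: fn(x)[1],
                                method="lm", xtol=1e-14, ftol=1e-14)
            cost_gn = fn(x_gn)[0] @ fn(x_gn)[0]
            assert cost_gn <= 2 * ref.cost * (1 + 1e-8) + 1e-12

    def test_motion_only_model_degenerate_shape_space(self, assets, camera,
                                                      sweep_sequence):
        core = assets.face_model.core_tensor[:, :1, :]
        model = ParametricFaceModel(core, assets.face_model.topology)
        obs = sweep_sequence.observations[0]
        params, pose, sf = fit_face_first_frame(obs, model, camera, assets.cmap)
        np.testing.assert_array_equal(params.shape, [1.0])
        assert sf.report.n_iter >= 1

    def test_tracking_fixed_point_on_identical_observation(self, assets, camera,
                                                           sweep_sequence):
        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        params, pose, _ = fit_face_frame(
            obs, truth, assets.face_model, camera, assets.cmap,
            SmoothingConfig(), TIGHT,
        )
        np.testing.assert_allclose(params.motion, truth.face.motion, atol=1e-9)
        np.testing.assert_allclose(pose.translation, truth.pose.translation,
                                   atol=1e-7)

    def test_infinite_smoothing_pins_to_previous(self, assets, camera,
                                                 sweep_sequence):
        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        pts = obs.face.points + 25.0  # grossly shifted landmarks
        from dataclasses import replace
        shifted = replace(obs, face=LandmarkSet2D("face", pts))
        heavy = SmoothingConfig(1e12, 1e12, 1e12, 1e12, 1e12, 1e12)
        params, pose, _ = fit_face_frame(
            shifted, truth, assets.face_model, camera, assets.cmap, heavy, TIGHT
        )
        np.testing.assert_allclose(params.motion, truth.face.motion, atol=1e-6)
        np.testing.assert_allclose(pose.translation, truth.pose.translation,
                                   atol=1e-4)
        np.testing.assert_allclose(pose.rotation, truth.pose.rotation, atol=1e-7)

    def test_zero_smoothing_equals_independent_fit(self, assets, camera,
                                                   sweep_sequence):
        obs = sweep_sequence.observations[5]
        truth5 = sweep_sequence.truth[5]
        for prev in (sweep_sequence.truth[4], sweep_sequence.truth[0]):
            params, pose, _ = fit_face_frame(
                obs, prev, assets.face_model, camera, assets.cmap,
                SmoothingConfig.disabled(), TIGHT,
            )
            np.testing.assert_allclose(params.motion, truth5.face.motion, atol=1e-7)
            np.testing.assert_allclose(pose.translation, truth5.pose.translation,
                                       atol=1e-5)


def gauss_newton_wrap(fn, x0):
    from ocumask import gauss_newton

    return gauss_newton(fn, x0, TIGHT)


# ---------------------------------------------------------------------------
# eyelid fitting


class TestEyelidFitting:
    def test_zero_noise_recovery(self, assets, camera, sweep_sequence):
        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        for eye in ("left", "right"):
            params, _ = fit_eyelid_first_frame(
                obs, truth.pose, assets.eyelid_models[eye], camera,
                assets.cmap, eye, TIGHT,
            )
            err = np.concatenate([
                params.shape - truth.eyelid[eye].shape,
                params.motion - truth.eyelid[eye].motion,
            ])
            assert np.sqrt(np.mean(err**2)) < 1e-5

    def test_semantic_energy_zero_when_vertices_on_lines(self, assets, camera,
                                                         sweep_sequence):
        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        proj = project_state(truth, assets, camera)
        e = semantic_line_energy(
            proj["eyelid_left"], obs.semantic_lines["left"],
            assets.cmap.semantic["left"],
        )
        assert e == pytest.approx(0.0, abs=1e-18)

    def test_semantic_energy_matches_brute_force_double_sum(self, assets, camera,
                                                            sweep_sequence, rng):
        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        proj = project_state(truth, assets, camera)
        pts = proj["eyelid_left"] + rng.normal(0, 1.5, proj["eyelid_left"].shape)
        e = semantic_line_energy(
            pts, obs.semantic_lines["left"], assets.cmap.semantic["left"]
        )
        oracle = 0.0
        for label, idx in assets.cmap.semantic["left"].items():
            line = obs.semantic_lines["left"][label]
            for j in idx:
                best = np.inf
                for a, b in zip(line[:-1], line[1:]):
                    ab = b - a
                    t = np.clip((pts[j] - a) @ ab / (ab @ ab), 0, 1)
                    best = min(best, np.sum((pts[j] - (a + t * ab)) ** 2))
                oracle += best
        assert e == pytest.approx(oracle, rel=1e-10)


# ---------------------------------------------------------------------------
# eyeball statics and gaze


class TestEyeballStatics:
    def test_kasa_circle_fit_matches_algebraic_oracle(self):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts = np.column_stack([3 + 5 * np.cos(ang), -2 + 5 * np.sin(ang)])
        center, radius = fit_circle_kasa(pts)
        A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(6)])
        b = (pts**2).sum(1)
        sol = np.linalg.solve(A.T @ A, A.T @ b)
        np.testing.assert_allclose(center, sol[:2], atol=1e-10)
        assert radius == pytest.approx(np.sqrt(sol[2] + sol[:2] @ sol[:2]), abs=1e-10)
        np.testing.assert_allclose(center, [3, -2], atol=1e-9)
        assert radius == pytest.approx(5.0, abs=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ContractViolationError):
            fit_circle_kasa(pts)

    def test_zero_noise_statics_recovery(self, assets, camera, sweep_sequence):
        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        params, pose, _ = fit_face_first_frame(
            obs, assets.face_model, camera, assets.cmap, TIGHT
        )
        face = reconstruct_face(assets.face_model, params)
        statics = estimate_eyeball_statics(obs, face, pose, camera, assets.cmap)
        for eye in ("left", "right"):
            st, tt = statics[eye], truth.statics[eye]
            assert st.r_e == pytest.approx(tt.r_e, abs=1e-6)
            assert st.r_i == pytest.approx(tt.r_i, abs=1e-6)
            np.testing.assert_allclose(st.p_e, tt.p_e, atol=1e-5)

    def test_too_few_iris_landmarks_rejected(self, assets, camera, sweep_sequence):
        from dataclasses import replace

        obs = sweep_sequence.observations[0]
        truth = sweep_sequence.truth[0]
        lm = obs.iris["left"]
        vis = np.zeros(len(lm), bool)
        vis[:2] = True
        crippled = replace(obs, iris={"left": LandmarkSet2D("iris", lm.points, vis),
                                      "right": obs.iris["right"]})
        face = reconstruct_face(assets.face_model, truth.face)
        with pytest.raises(InsufficientDataError):
            estimate_eyeball_statics(crippled, face, truth.pose, camera, assets.cmap)


class TestGazeFitting:
    def test_gaze_sweep_recovery_within_tenth_degree(self, assets, camera,
                                                     sweep_sequence):
        for k in (2, 5, 8):
            obs = sweep_sequence.observations[k]
            truth = sweep_sequence.truth[k]
            gaze, _ = fit_eyeball_frame(
                obs, truth.statics["left"], truth.pose, camera, assets.cmap,
                "left", prev_gaze=EyeballRotation(0.0, 0.0),
                smoothing=SmoothingConfig.disabled(), solver=TIGHT,
            )
            assert abs(np.rad2deg(gaze.theta - truth.gaze["left"].theta)) < 0.1
            assert abs(np.rad2deg(gaze.phi - truth.gaze["left"].phi)) < 0.1

    def test_grid_search_oracle_agrees(self, assets, camera, sweep_sequence):
        k = 3
        obs = sweep_sequence.observations[k]
        truth = sweep_sequence.truth[k]
        st = truth.statics["left"]
        ball = eyeball_mesh(
            EyeballModel(st.r_e, st.r_i, st.p_e, assets.n_lat, assets.n_lon,
                         assets.n_iris)
        ).vertices
        lm = obs.iris["left"]
        fn = _eyeball_residual_builder(
            ball, assets.cmap.iris["left"], lm.visibility, lm.points, st.p_e,
            truth.pose, camera,
        )
        gaze, _ = fit_eyeball_frame(
            obs, st, truth.pose, camera, assets.cmap, "left",
            solver=TIGHT, ball_vertices=ball,
        )
        step = np.deg2rad(0.05)
        grid = np.arange(-np.deg2rad(2), np.deg2rad(2) + step / 2, step)
        best, arg = np.inf, None
        for th in grid + truth.gaze["left"].theta:
            for ph in grid + truth.gaze["left"].phi:
                r, _ = fn(np.array([th, ph]))
                c = r @ r
                if c < best:
                    best, arg = c, (th, ph)
        assert abs(gaze.theta - arg[0]) <= step
        assert abs(gaze.phi - arg[1]) <= step

    def test_infinite_smoothing_pins_gaze(self, assets, camera, sweep_sequence):
        obs = sweep_sequence.observations[4]
        truth = sweep_sequence.truth[4]
        prev = EyeballRotation(0.123, -0.045)
        heavy = SmoothingConfig(0, 0, 0, 0, 1e14, 1e14)
        gaze, _ = fit_eyeball_frame(
            obs, truth.statics["left"], truth.pose, camera, assets.cmap, "left",
            prev_gaze=prev, smoothing=heavy, solver=TIGHT,
        )
        assert gaze.theta == pytest.approx(prev.theta, abs=1e-5)
        assert gaze.phi == pytest.approx(prev.phi, abs=1e-5)

    def test_occluded_eye_inherits_previous_gaze(self, assets, camera,
                                                 sweep_sequence):
        from dataclasses import replace

        obs = sweep_sequence.observations[4]
        truth = sweep_sequence.truth[4]
        lm = obs.iris["left"]
        hidden = replace(
            obs, iris={"left": LandmarkSet2D("iris", lm.points,
                                             np.zeros(len(lm), bool)),
                       "right": obs.iris["right"]},
        )
        prev = EyeballRotation(0.07, 0.02)
        gaze, sf = fit_eyeball_frame(
            hidden, truth.statics["left"], truth.pose, camera, assets.cmap,
            "left", prev_gaze=prev,
        )
        assert (gaze.theta, gaze.phi) == (prev.theta, prev.phi)
        assert sf.n_residual_rows == 0
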