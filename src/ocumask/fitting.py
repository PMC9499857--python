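"""The three-stage reconstruction: face, eyelid, eyeball fitting.

Each video frame is processed in a fixed order.  First the face stage
recovers rigid pose and bilinear face weights from face landmarks; then the
eyelid stage recovers eyelid weights from densified eyelid landmarks plus
the four semantic lines, with the pose held fixed; finally the eyeball stage
recovers the two gaze angles from iris landmarks.  Shape-type parameters
(face shape weights, eyelid shape weights, eyeball radii and position) are
estimated on the first frame only and frozen afterwards; later frames add
quadratic temporal-smoothing penalties pulling the dynamics toward the
previous frame.

All stages share the damped Gauss-Newton solver and supply analytic
Jacobians; rotations are optimised through an axis-angle chart anchored at
the initial rotation, so the recovered rotation is orthonormal by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .config import PriorConfig, SmoothingConfig
from .errors import ContractViolationError, InsufficientDataError
from .features import (
    EYES,
    LIDS,
    CorrespondenceMap,
    DenseEyelidLandmarks,
    FrameObservation,
    LandmarkSet2D,
    densify,
    fit_eyelid_curve,
    polyline_closest_point,
)
from .liegroup import exp_so3, hat, right_jacobian
from .models import (
    Camera,
    EyeballModel,
    EyeballRotation,
    EyelidModel,
    EyelidParams,
    FaceParams,
    ParametricFaceModel,
    RigidPose,
    eyeball_mesh,
    reconstruct_eyelid,
    reconstruct_face,
)
from .solver import ConvergenceReport, SolverConfig, gauss_newton
from .state import EyeballStatics, FitState


# ---------------------------------------------------------------------------
# energies (public, used directly by tests and diagnostics)


def face_energy(
    model: ParametricFaceModel,
    params: FaceParams,
    pose: RigidPose,
    camera: Camera,
    cmap: CorrespondenceMap,
    landmarks: LandmarkSet2D,
) -> Tuple[float, np.ndarray]:
    """Landmark registration energy of the face stage.

    Returns the scalar energy (sum of squared pixel distances between
    visible landmarks and the projections of their corresponding posed face
    vertices) and the stacked per-landmark 2D residual vector.  Occluded
    landmarks contribute nothing.
    """
    vis = landmarks.visibility
    if not vis.any():
        raise InsufficientDataError("no visible face landmarks")
    M = reconstruct_face(model, params)
    v = M[cmap.face[vis]] @ pose.rotation.T + pose.translation
    r = (camera.project(v) - landmarks.points[vis]).ravel()
    return float(r @ r), r


def semantic_line_energy(
    projected: np.ndarray, semantic, vertex_sets: Dict[str, np.ndarray]
) -> float:
    """Sum over lines k and vertices j in v_sl(k) of dis(proj_j, S_k)^2."""
    total = 0.0
    for label, idx in vertex_sets.items():
        if label not in semantic:
            continue
        line = semantic[label]
        for j in idx:
            q = polyline_closest_point(projected[j], line)
            total += float(((projected[j] - q) ** 2).sum())
    return total


# ---------------------------------------------------------------------------
# initialization


def umeyama_2d(src: np.ndarray, dst: np.ndarray):
    """Closed-form similarity (s, R, t) minimising ||s R src + t - dst||^2."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    mu_s, mu_d = src.mean(0), dst.mean(0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / src.shape[0]
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[1, 1] = -1
    R = U @ S @ Vt
    var_s = (xs**2).sum() / src.shape[0]
    s = np.trace(np.diag(D) @ S) / var_s
    t = mu_d - s * R @ mu_s
    return s, R, t


def initial_pose_estimate(
    obs: FrameObservation,
    model: ParametricFaceModel,
    camera: Camera,
    cmap: CorrespondenceMap,
) -> RigidPose:
    """Frame-0 pose seed from a 2D similarity alignment of the mean face.

    The mean-model landmark xy coordinates are aligned to the observed
    landmarks; the in-plane rotation seeds R, the scale seeds the depth
    (pinhole) or is consistent with the configured scale (weak perspective).
    """
    params = FaceParams(
        np.eye(model.n_shape)[0] if model.n_shape else np.ones(0),
        np.eye(model.n_motion)[0] if model.n_motion else np.ones(0),
    )
    M = reconstruct_face(model, params)
    vis = obs.face.visibility
    src = M[cmap.face[vis]][:, :2]
    dst = obs.face.points[vis]
    s, R2, t2 = umeyama_2d(src, dst)
    R = np.eye(3)
    R[:2, :2] = R2
    if camera.mode == "pinhole":
        z0 = camera.focal / s
        t_xy = (t2 - camera.principal) * z0 / camera.focal
        t = np.array([t_xy[0], t_xy[1], z0])
    else:
        t_xy = (t2 - camera.principal) / camera.scale
        t = np.array([t_xy[0], t_xy[1], 0.0])
    return RigidPose(R, t)


# ---------------------------------------------------------------------------
# face stage


@dataclass
class StageFit:
    """Outcome of one fitting stage on one frame."""

    report: ConvergenceReport
    n_residual_rows: int


def _face_motion_derivative(core, shape_w, motion_w):
    """(d M/d w_shape, d M/d w_motion) as (3N, n_s) and (3N, n_m) arrays."""
    dMs = np.einsum("ksm,m->ks", core, motion_w)
    dMm = np.einsum("ksm,s->km", core, shape_w)
    return dMs, dMm


def _face_residual_builder(
    model,
    camera,
    cmap,
    landmarks: LandmarkSet2D,
    R_ref: np.ndarray,
    fit_shape: bool,
    fixed_shape: np.ndarray,
    prev: Optional[dict] = None,
    smoothing: Optional[SmoothingConfig] = None,
):
    """Residual/Jacobian callback over x = [w_fs_free?, w_fm_free, delta, t].

    The leading entry of each weight vector is pinned to 1 (gauge fix for the
    bilinear scale ambiguity), so only the trailing entries are optimised.
    """
    vis = landmarks.visibility
    if not vis.any():
        raise InsufficientDataError("no visible face landmarks")
    idx = cmap.face[vis]
    L = landmarks.points[vis]
    n_s = model.n_shape - 1 if fit_shape else 0
    n_m = model.n_motion - 1
    sel3 = np.stack([3 * idx, 3 * idx + 1, 3 * idx + 2], axis=1)  # (n, 3)

    def unpack(x):
        o = 0
        if fit_shape:
            ws = np.concatenate([[1.0], x[:n_s]])
            o = n_s
        else:
            ws = fixed_shape
        wm = np.concatenate([[1.0], x[o : o + n_m]])
        delta = x[o + n_m : o + n_m + 3]
        t = x[o + n_m + 3 :]
        return ws, wm, delta, t

    def fn(x):
        ws, wm, delta, t = unpack(x)
        E = exp_so3(delta)
        Jr = right_jacobian(delta)
        Rtot = E @ R_ref
        M = np.einsum("ksm,s,m->k", model.core_tensor, ws, wm)
        m = M.reshape(-1, 3)[idx]  # (n, 3) model frame
        w = m @ R_ref.T  # after anchor rotation
        v = w @ E.T + t
        p = camera.project(v)
        r = (p - L).ravel()
        A = camera.jacobian(v)  # (n, 2, 3)
        cols = []
        if fit_shape or n_m:
            dMs, dMm = _face_motion_derivative(model.core_tensor, ws, wm)
        if fit_shape and n_s:
            dm = dMs[:, 1:][sel3.ravel()].reshape(-1, 3, n_s)  # (n,3,n_s)
            cols.append(np.einsum("nij,jk,nkl->nil", A, Rtot, dm))
        if n_m:
            dm = dMm[:, 1:][sel3.ravel()].reshape(-1, 3, n_m)
            cols.append(np.einsum("nij,jk,nkl->nil", A, Rtot, dm))
        # rotation: dv/ddelta = -E [w]x J_r(delta)
        W = np.stack([hat(wi) for wi in w])
        dvdd = -np.einsum("ij,njk,kl->nil", E, W, Jr)
        cols.append(np.einsum("nij,njk->nik", A, dvdd))
        cols.append(A)  # translation
        J = np.concatenate(cols, axis=2).reshape(r.shape[0], -1)
        if smoothing is not None and prev is not None:
            rows, jrows = _face_smoothing_rows(
                x, ws, wm, delta, t, E, Jr, R_ref, prev, smoothing,
                fit_shape, n_s, n_m,
            )
            r = np.concatenate([r, rows])
            J = np.vstack([J, jrows])
        return r, J

    return fn, unpack


def _face_smoothing_rows(
    x, ws, wm, delta, t, E, Jr, R_ref, prev, smoothing, fit_shape, n_s, n_m
):
    npar = x.shape[0]
    rows, jrows = [], []
    o = n_s if fit_shape else 0
    if smoothing.lambda_fm > 0 and n_m:
        s = np.sqrt(smoothing.lambda_fm)
        rows.append(s * (wm[1:] - prev["wm"][1:]))
        Jb = np.zeros((n_m, npar))
        Jb[:, o : o + n_m] = s * np.eye(n_m)
        jrows.append(Jb)
    if smoothing.lambda_R > 0:
        s = np.sqrt(smoothing.lambda_R)
        Rcur = E @ R_ref
        rows.append(s * (Rcur - prev["R"]).ravel())
        Jb = np.zeros((9, npar))
        for k in range(3):
            dE = E @ hat(Jr[:, k])
            Jb[:, o + n_m + k] = s * (dE @ R_ref).ravel()
        jrows.append(Jb)
    if smoothing.lambda_t > 0:
        s = np.sqrt(smoothing.lambda_t)
        rows.append(s * (t - prev["t"]))
        Jb = np.zeros((3, npar))
        Jb[:, o + n_m + 3 :] = s * np.eye(3)
        jrows.append(Jb)
    if rows:
        return np.concatenate(rows), np.vstack(jrows)
    return np.zeros(0), np.zeros((0, npar))


def fit_face_first_frame(
    obs: FrameObservation,
    model: ParametricFaceModel,
    camera: Camera,
    cmap: CorrespondenceMap,
    solver: Optional[SolverConfig] = None,
    init_params: Optional[FaceParams] = None,
    init_pose: Optional[RigidPose] = None,
) -> Tuple[FaceParams, RigidPose, StageFit]:
    """Estimate (w_fs, w_fm, R, t) from the first frame's face landmarks."""
    solver = solver or SolverConfig()
    if init_pose is None:
        init_pose = initial_pose_estimate(obs, model, camera, cmap)
    if init_params is None:
        init_params = FaceParams(
            np.concatenate([[1.0], np.zeros(model.n_shape - 1)]),
            np.concatenate([[1.0], np.zeros(model.n_motion - 1)]),
        )
    R_ref = init_pose.rotation
    fn, unpack = _face_residual_builder(
        model, camera, cmap, obs.face, R_ref, True, init_params.shape
    )
    x0 = np.concatenate(
        [init_params.shape[1:], init_params.motion[1:], np.zeros(3),
         init_pose.translation]
    )
    x, report = gauss_newton(fn, x0, solver)
    ws, wm, delta, t = unpack(x)
    pose = RigidPose(exp_so3(delta) @ R_ref, t)
    n_rows = 2 * int(obs.face.visibility.sum())
    return FaceParams(ws, wm), pose, StageFit(report, n_rows)


def fit_face_frame(
    obs: FrameObservation,
    prev: FitState,
    model: ParametricFaceModel,
    camera: Camera,
    cmap: CorrespondenceMap,
    smoothing: Optional[SmoothingConfig] = None,
    solver: Optional[SolverConfig] = None,
) -> Tuple[FaceParams, RigidPose, StageFit]:
    """Track (w_fm, R, t) on a later frame; w_fs stays frozen from frame 0.

    Minimises the landmark energy plus the temporal smoothing penalties on
    motion weights, rotation (Frobenius norm) and translation.
    """
    solver = solver or SolverConfig()
    smoothing = smoothing if smoothing is not None else SmoothingConfig()
    R_ref = prev.pose.rotation
    prev_blob = {"wm": prev.face.motion, "R": prev.pose.rotation,
                 "t": prev.pose.translation}
    fn, unpack = _face_residual_builder(
        model, camera, cmap, obs.face, R_ref, False, prev.face.shape,
        prev=prev_blob, smoothing=smoothing,
    )
    x0 = np.concatenate([prev.face.motion[1:], np.zeros(3), prev.pose.translation])
    x, report = gauss_newton(fn, x0, solver)
    ws, wm, delta, t = unpack(x)
    pose = RigidPose(exp_so3(delta) @ R_ref, t)
    n_rows = 2 * int(obs.face.visibility.sum())
    return FaceParams(prev.face.shape, wm), pose, StageFit(report, n_rows)


# ---------------------------------------------------------------------------
# eyelid stage


def build_dense_landmarks(
    obs: FrameObservation, eye: str, cmap: CorrespondenceMap
) -> Dict[str, DenseEyelidLandmarks]:
    """Cubic-fit + uniform resampling of the sparse eyelid landmarks.

    Lids with fewer than two visible landmarks are omitted (their dense
    term is dropped from the energy).
    """
    out = {}
    for lid in LIDS:
        lm = obs.eyelid[eye][lid]
        if lm.visibility.sum() < 2:
            continue
        curve = fit_eyelid_curve(lm)
        n = len(cmap.eyelid[eye][lid])
        out[lid] = densify(curve, n, source=f"{eye}/{lid}")
    return out


def _eyelid_residual_builder(
    model: EyelidModel,
    camera: Camera,
    cmap: CorrespondenceMap,
    eye: str,
    dense: Dict[str, DenseEyelidLandmarks],
    semantic,
    pose: RigidPose,
    fit_shape: bool,
    fixed_shape: np.ndarray,
    prev_motion: Optional[np.ndarray] = None,
    smoothing: Optional[SmoothingConfig] = None,
):
    n_s = model.n_shape if fit_shape else 0
    n_m = model.n_motion
    S = model.shape_basis.T.reshape(-1, 3, model.n_shape)  # (N, 3, n_s)
    B = model.motion_basis.T.reshape(-1, 3, model.n_motion)
    R, t = pose.rotation, pose.translation

    sem_sets = {}
    if semantic is not None:
        for label, idx in cmap.semantic[eye].items():
            if label in semantic:
                sem_sets[label] = idx
            else:
                warnings.warn(
                    f"semantic line {label!r} missing for {eye} eye; term dropped",
                    stacklevel=3,
                )

    def unpack(x):
        ws = x[:n_s] if fit_shape else fixed_shape
        wm = x[n_s : n_s + n_m]
        return ws, wm

    def fn(x):
        ws, wm = unpack(x)
        verts = reconstruct_eyelid(model, EyelidParams(ws, wm))
        v = verts @ R.T + t
        p = camera.project(v)
        A = camera.jacobian(v)
        rows, jrows = [], []
        for lid, dl in dense.items():
            idx = cmap.eyelid[eye][lid]
            r = (p[idx] - dl.points).ravel()
            blocks = []
            if fit_shape:
                blocks.append(np.einsum("nij,jk,nkl->nil", A[idx], R, S[idx]))
            blocks.append(np.einsum("nij,jk,nkl->nil", A[idx], R, B[idx]))
            rows.append(r)
            jrows.append(np.concatenate(blocks, axis=2).reshape(r.shape[0], -1))
        for label, idx in sem_sets.items():
            line = semantic[label]
            for j in idx:
                q = polyline_closest_point(p[j], line)
                diff = p[j] - q
                d = float(np.hypot(*diff))
                rows.append([d])
                if d > 0:
                    g = diff / d  # gradient of point-to-set distance
                else:
                    g = np.zeros(2)
                blocks = []
                if fit_shape:
                    blocks.append(g @ A[j] @ R @ S[j])
                blocks.append(g @ A[j] @ R @ B[j])
                jrows.append(np.concatenate(blocks)[None, :])
        if smoothing is not None and smoothing.lambda_em > 0 and prev_motion is not None:
            s = np.sqrt(smoothing.lambda_em)
            rows.append(s * (wm - prev_motion))
            Jb = np.zeros((n_m, n_s + n_m))
            Jb[:, n_s:] = s * np.eye(n_m)
            jrows.append(Jb)
        r = np.concatenate([np.atleast_1d(np.asarray(b, float)) for b in rows])
        J = np.vstack(jrows)
        return r, J

    return fn, unpack


def _eyelid_row_count(dense, cmap, eye, semantic):
    n = sum(2 * len(dl.points) for dl in dense.values())
    if semantic is not None:
        for label, idx in cmap.semantic[eye].items():
            if label in semantic:
                n += len(idx)
    return n


def fit_eyelid_first_frame(
    obs: FrameObservation,
    pose: RigidPose,
    model: EyelidModel,
    camera: Camera,
    cmap: CorrespondenceMap,
    eye: str,
    solver: Optional[SolverConfig] = None,
) -> Tuple[EyelidParams, StageFit]:
    """Joint (w_es, w_em) estimate on frame 0 for one eye."""
    solver = solver or SolverConfig()
    dense = build_dense_landmarks(obs, eye, cmap)
    if not dense:
        raise InsufficientDataError(f"no usable eyelid landmarks for {eye} eye")
    semantic = obs.semantic_lines.get(eye)
    fn, unpack = _eyelid_residual_builder(
        model, camera, cmap, eye, dense, semantic, pose, True, np.zeros(model.n_shape)
    )
    x0 = np.zeros(model.n_shape + model.n_motion)
    x, report = gauss_newton(fn, x0, solver)
    ws, wm = unpack(x)
    return EyelidParams(ws, wm), StageFit(
        report, _eyelid_row_count(dense, cmap, eye, semantic)
    )


def fit_eyelid_frame(
    obs: FrameObservation,
    prev: FitState,
    pose: RigidPose,
    model: EyelidModel,
    camera: Camera,
    cmap: CorrespondenceMap,
    eye: str,
    smoothing: Optional[SmoothingConfig] = None,
    solver: Optional[SolverConfig] = None,
) -> Tuple[EyelidParams, StageFit]:
    """Track w_em on a later frame; w_es stays frozen from frame 0."""
    solver = solver or SolverConfig()
    smoothing = smoothing if smoothing is not None else SmoothingConfig()
    dense = build_dense_landmarks(obs, eye, cmap)
    prev_params = prev.eyelid[eye]
    semantic = obs.semantic_lines.get(eye)
    have_semantic = semantic is not None and any(
        label in semantic for label in cmap.semantic[eye]
    )
    if not dense and not have_semantic:
        return EyelidParams(prev_params.shape, prev_params.motion), StageFit(
            ConvergenceReport(True, "no_data_inherit_prev", 0, 0.0), 0
        )
    fn, unpack = _eyelid_residual_builder(
        model, camera, cmap, eye, dense, semantic, pose, False, prev_params.shape,
        prev_motion=prev_params.motion, smoothing=smoothing,
    )
    x, report = gauss_newton(fn, prev_params.motion.copy(), solver)
    _, wm = unpack(x)
    return EyelidParams(prev_params.shape, wm), StageFit(
        report, _eyelid_row_count(dense, cmap, eye, semantic)
    )


# ---------------------------------------------------------------------------
# eyeball stage


def fit_circle_kasa(points: np.ndarray) -> Tuple[np.ndarray, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (center, radius)."""
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] < 3:
        raise InsufficientDataError("circle fit needs >= 3 points")
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(pts.shape[0])])
    b = (pts**2).sum(axis=1)
    try:
        sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ContractViolationError("degenerate circle fit") from exc
    if rank < 3:
        raise ContractViolationError("iris points are collinear; circle fit degenerate")
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        raise ContractViolationError("degenerate circle fit (non-positive radius)")
    return np.array([cx, cy]), float(np.sqrt(r2))


def eye_region_centroids(
    face_vertices: np.ndarray, cmap: CorrespondenceMap
) -> Dict[str, np.ndarray]:
    """Centroid of each eye's designated face-vertex region (face-local)."""
    return {eye: face_vertices[cmap.face_eye_region[eye]].mean(axis=0) for eye in EYES}


def prior_radius_and_position(
    face_vertices: np.ndarray, cmap: CorrespondenceMap, priors: PriorConfig
) -> Dict[str, Tuple[float, np.ndarray]]:
    """Prior-driven eyeball radius and centre for both eyes.

    The eyeball radius is a fixed fraction of the distance between the two
    eye-region centroids of the fitted face; the centre sits behind the
    centroid (along +z, away from the camera) by a fixed fraction of the
    radius.  The same convention is used by the synthetic generator, so on
    synthetic data the prior is exact.
    """
    cen = eye_region_centroids(face_vertices, cmap)
    d = float(np.linalg.norm(cen["left"] - cen["right"]))
    if d <= 0:
        raise ContractViolationError("coincident eye-region centroids")
    r_e = priors.radius_ratio * d
    out = {}
    for eye in EYES:
        p_e = cen[eye] + np.array([0.0, 0.0, priors.depth_ratio * r_e])
        out[eye] = (r_e, p_e)
    return out


def estimate_eyeball_statics(
    obs: FrameObservation,
    face_vertices: np.ndarray,
    pose: RigidPose,
    camera: Camera,
    cmap: CorrespondenceMap,
    priors: Optional[PriorConfig] = None,
) -> Dict[str, EyeballStatics]:
    """First-frame estimate of (r_e, r_i, p_e) per eye, fixed thereafter.

    The radius and position come from the face-scaled prior; the iris radius
    comes from a Kasa circle fit to the visible iris landmarks, back-projected
    at the depth of the iris plane (which for a near-frontal first frame is a
    frontoparallel circle).
    """
    priors = priors or PriorConfig()
    rp = prior_radius_and_position(face_vertices, cmap, priors)
    out = {}
    for eye in EYES:
        lm = obs.iris[eye]
        pts = lm.visible_points
        if pts.shape[0] < 3:
            raise InsufficientDataError(
                f"need >= 3 visible iris landmarks for {eye} eye, got {pts.shape[0]}"
            )
        _, rho = fit_circle_kasa(pts)
        r_e, p_e = rp[eye]
        if camera.mode == "weak_perspective":
            r_i = rho / camera.scale
        else:
            z_c = float((pose.rotation @ p_e + pose.translation)[2])

            def g(ri):
                return ri - rho * (z_c - np.sqrt(r_e**2 - ri**2)) / camera.focal

            hi = r_e * (1 - 1e-12)
            if g(hi) <= 0:
                raise ContractViolationError(
                    "iris circle fit larger than the eyeball prior allows"
                )
            r_i = float(brentq(g, 1e-9 * r_e, hi, xtol=1e-14))
        out[eye] = EyeballStatics(r_e, r_i, p_e)
    return out


def _eyeball_residual_builder(
    ball_vertices: np.ndarray,
    iris_idx: np.ndarray,
    vis: np.ndarray,
    L: np.ndarray,
    p_e: np.ndarray,
    pose: RigidPose,
    camera: Camera,
    prev_angles: Optional[Tuple[float, float]] = None,
    smoothing: Optional[SmoothingConfig] = None,
):
    Bsel = ball_vertices[iris_idx[vis]]
    Lsel = L[vis]
    R, t = pose.rotation, pose.translation

    def fn(x):
        theta, phi = x
        ct, st = np.cos(theta), np.sin(theta)
        cp, sp = np.cos(phi), np.sin(phi)
        Rx = np.array([[1, 0, 0], [0, ct, -st], [0, st, ct]])
        Ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
        dRx = np.array([[0, 0, 0], [0, -st, -ct], [0, ct, -st]])
        dRy = np.array([[-sp, 0, cp], [0, 0, 0], [-cp, 0, -sp]])
        rot = Rx @ Ry
        v = (Bsel @ rot.T + p_e) @ R.T + t
        p = camera.project(v)
        r = (p - Lsel).ravel()
        A = camera.jacobian(v)
        dth = Bsel @ (dRx @ Ry).T @ R.T
        dph = Bsel @ (Rx @ dRy).T @ R.T
        J = np.stack(
            [
                np.einsum("nij,nj->ni", A, dth).ravel(),
                np.einsum("nij,nj->ni", A, dph).ravel(),
            ],
            axis=1,
        )
        if smoothing is not None and prev_angles is not None:
            rows = []
            jrows = []
            if smoothing.lambda_theta > 0:
                s = np.sqrt(smoothing.lambda_theta)
                rows.append(s * (theta - prev_angles[0]))
                jrows.append([s, 0.0])
            if smoothing.lambda_phi > 0:
                s = np.sqrt(smoothing.lambda_phi)
                rows.append(s * (phi - prev_angles[1]))
                jrows.append([0.0, s])
            if rows:
                r = np.concatenate([r, rows])
                J = np.vstack([J, np.asarray(jrows)])
        return r, J

    return fn


def fit_eyeball_frame(
    obs: FrameObservation,
    statics: EyeballStatics,
    pose: RigidPose,
    camera: Camera,
    cmap: CorrespondenceMap,
    eye: str,
    prev_gaze: Optional[EyeballRotation] = None,
    smoothing: Optional[SmoothingConfig] = None,
    solver: Optional[SolverConfig] = None,
    ball_vertices: Optional[np.ndarray] = None,
) -> Tuple[EyeballRotation, StageFit]:
    """Recover gaze angles (theta, phi) for one eye on one frame.

    An eye with fewer than three visible iris landmarks inherits the
    previous frame's gaze.
    """
    solver = solver or SolverConfig()
    lm = obs.iris[eye]
    vis = lm.visibility
    if vis.sum() < 3:
        if prev_gaze is None:
            raise InsufficientDataError(
                f"<3 visible iris landmarks on the first frame for {eye} eye"
            )
        return EyeballRotation(prev_gaze.theta, prev_gaze.phi), StageFit(
            ConvergenceReport(True, "occluded_inherit_prev", 0, 0.0), 0
        )
    if ball_vertices is None:
        ball_vertices = eyeball_mesh(
            EyeballModel(statics.r_e, statics.r_i)
        ).vertices
    prev_angles = (prev_gaze.theta, prev_gaze.phi) if prev_gaze is not None else None
    sm = smoothing if prev_gaze is not None else None
    fn = _eyeball_residual_builder(
        ball_vertices, cmap.iris[eye], vis, lm.points, statics.p_e, pose, camera,
        prev_angles=prev_angles, smoothing=sm,
    )
    x0 = np.array(prev_angles) if prev_angles is not None else np.zeros(2)
    x, report = gauss_newton(fn, x0, solver)
    return EyeballRotation(float(x[0]), float(x[1])), StageFit(
        report, 2 * int(vis.sum())
    )
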