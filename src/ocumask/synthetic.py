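"""Synthetic model assets and ground-truth-parameterised landmark streams.

The production model assets of a real deployment (a statistically learned
face core tensor, scanned eyelid bases) are proprietary; this module builds
small assets with the same mathematical structure — a bilinear face around a
face-like template grid with designated eye sockets, per-eye eyelid chain
models whose bases act on the vertical coordinate, and spherical eyeballs —
and synthesises "examination video" feature streams by projecting known
parameter trajectories, optionally adding detector noise and occlusion.

The motif library is a set of geometric caricatures of clinical signs
(fixation, gaze sweep, fixed strabismic offset, ptotic droop, nystagmus
oscillation, blink); they exercise the reconstruction machinery and are not
clinical simulations.

Design notes that make zero-noise recovery exact (and are therefore shared
contracts with the fitting stages):

* eyelid chains have constant depth and polynomial (degree <= 3) vertical
  profiles, and the bases perturb only the vertical coordinate, so a pinhole
  projection of a chain is again a cubic in image x and uniform model-x
  spacing stays uniform in the image;
* every motif starts from a frontal pose with neutral gaze, matching the
  first-frame conventions used by the static-eyeball estimator;
* sparse eyelid landmarks are chain vertices (endpoints included), so the
  densified curve resamples exactly onto the projected chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .config import PriorConfig
from .features import (
    EYES,
    SEMANTIC_LABELS,
    CorrespondenceMap,
    FrameObservation,
    LandmarkSet2D,
    SemanticLineSet,
)
from .fitting import prior_radius_and_position
from .models import (
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
    reconstruct_eyelid,
    reconstruct_face,
)
from .state import EyeballStatics, FitState

MOTIFS = ("fixation", "gaze_sweep", "strabismus", "ptosis", "nystagmus", "blink")

CHAIN_ORDER = SEMANTIC_LABELS  # fold, upper, lower, bulge


@dataclass
class SyntheticAssetSpec:
    """Dimensions and seed of a synthetic asset archive."""

    nx: int = 12  # face grid columns
    ny: int = 10  # face grid rows
    n_shape: int = 4  # face shape dimension (leading entry pinned to 1)
    n_motion: int = 3  # face motion dimension
    chain_len: int = 25  # vertices per eyelid chain
    n_eyelid_shape: int = 3
    n_eyelid_motion: int = 2
    n_sparse: int = 7  # detected eyelid landmarks per lid
    n_lat: int = 7  # eyeball sphere latitudes
    n_lon: int = 12
    n_iris: int = 19  # iris-ring vertices = iris landmarks per eye
    n_face_landmarks: int = 20
    scale: float = 1.0  # global geometry scale, model units
    seed: int = 7


@dataclass
class Assets:
    """A complete model-asset bundle: models + correspondence maps."""

    face_model: ParametricFaceModel
    eyelid_models: Dict[str, EyelidModel]
    cmap: CorrespondenceMap
    n_lat: int
    n_lon: int
    n_iris: int
    eyelid_sample_idx: np.ndarray
    metadata: dict = field(default_factory=dict)


def _poly_fields(rng, u, w, n_fields, amp):
    """Smooth random 3D displacement fields over normalised grid coords.

    Quadratic and cubic monomials only: constant and linear terms are
    excluded so no field mimics a global translation or affine pose change.
    """
    basis = np.stack(
        [u**2, u * w, w**2, u**3, u**2 * w, u * w**2, w**3], axis=1
    )  # (N, 7)
    fields = []
    for _ in range(n_fields):
        coef = rng.standard_normal((7, 3)) * amp
        fields.append((basis @ coef).ravel())  # (3N,) interleaved xyz
    return fields


def generate_assets(spec: Optional[SyntheticAssetSpec] = None) -> Assets:
    """Build a seed-deterministic synthetic asset bundle."""
    spec = spec or SyntheticAssetSpec()
    rng = np.random.default_rng(spec.seed)
    sc = spec.scale

    # --- face template: grid over the face, dome toward the camera (-z)
    xs = np.linspace(-60, 60, spec.nx) * sc
    ys = np.linspace(-70, 50, spec.ny) * sc  # y down: forehead -> chin
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    gx, gy = gx.ravel(), gy.ravel()
    gz = -22 * sc * np.exp(-(((gx / (55 * sc)) ** 2) + ((gy + 10 * sc) ** 2 / (55 * sc) ** 2)))
    template = np.column_stack([gx, gy, gz])
    n_face = template.shape[0]

    tris = []
    for j in range(spec.ny - 1):
        for i in range(spec.nx - 1):
            a = j * spec.nx + i
            tris.append([a, a + 1, a + spec.nx])
            tris.append([a + 1, a + spec.nx + 1, a + spec.nx])
    topology = np.asarray(tris, dtype=int)

    u, w = gx / (60 * sc), gy / (60 * sc)
    core = np.zeros((3 * n_face, spec.n_shape, spec.n_motion))
    core[:, 0, 0] = template.ravel()
    for s, f in enumerate(
        _poly_fields(rng, u, w, spec.n_shape - 1, 2.5 * sc), start=1
    ):
        core[:, s, 0] = f
    # motion fields: brow raise and lower-face movement, plus mild randomness
    g_brow = np.exp(-(((gy + 25 * sc) / (12 * sc)) ** 2)) * np.exp(-((gx / (45 * sc)) ** 2))
    g_jaw = np.exp(-(((gy - 40 * sc) / (15 * sc)) ** 2))
    motions = []
    if spec.n_motion > 1:
        m1 = np.zeros((n_face, 3))
        m1[:, 1] = -5 * sc * g_brow
        m1[:, 2] = -1 * sc * g_brow
        motions.append(m1.ravel())
    if spec.n_motion > 2:
        m2 = np.zeros((n_face, 3))
        m2[:, 1] = 4 * sc * g_jaw
        motions.append(m2.ravel())
    for m in range(3, spec.n_motion):
        motions.append(_poly_fields(rng, u, w, 1, 1.0 * sc)[0])
    for m, f in enumerate(motions, start=1):
        core[:, 0, m] = f + _poly_fields(rng, u, w, 1, 0.3 * sc)[0]
    for s in range(1, spec.n_shape):
        for m in range(1, spec.n_motion):
            core[:, s, m] = _poly_fields(rng, u, w, 1, 0.3 * sc)[0]

    face_model = ParametricFaceModel(core, topology)

    # --- regions and face landmarks
    eye_centers = {"left": np.array([20.0, -10.0]) * sc,
                   "right": np.array([-20.0, -10.0]) * sc}
    face_eye_region = {}
    face_brow_region = {}
    for eye, c in eye_centers.items():
        d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2
        face_eye_region[eye] = np.flatnonzero(d2 <= (16 * sc) ** 2)
        in_brow = (
            (gy >= -45 * sc) & (gy <= -20 * sc) & (np.abs(gx - c[0]) <= 20 * sc)
        )
        face_brow_region[eye] = np.flatnonzero(in_brow)
    c_face = np.arange(0, n_face, max(1, n_face // spec.n_face_landmarks))[
        : spec.n_face_landmarks
    ]

    # --- eyelid models (one per eye), four chains of chain_len vertices
    L = spec.chain_len
    xi = np.linspace(-1.0, 1.0, L)
    bump = 1 - xi**2
    eyelid_models = {}
    c_eyelid = {}
    c_semantic = {}
    eyelid_brow_region = {}
    half = 14 * sc
    for eye, c in eye_centers.items():
        ex, ey = c
        zeye = -14 * sc
        x = ex + half * xi
        chains = {}
        a3 = rng.normal(0, 0.2 * sc, size=4)  # mild per-chain asymmetry
        y_up = ey - 2 * sc - 4 * sc * bump + a3[0] * xi**3
        chains["upper_eyelid"] = np.column_stack(
            [x, y_up, np.full(L, zeye - 1.0 * sc)]
        )
        chains["double_fold"] = np.column_stack(
            [x, y_up - 2.5 * sc - 0.5 * sc * bump + a3[1] * xi**3,
             np.full(L, zeye - 0.5 * sc)]
        )
        y_low = ey + 1 * sc + 2 * sc * bump + a3[2] * xi**3
        chains["lower_eyelid"] = np.column_stack(
            [x, y_low, np.full(L, zeye - 0.8 * sc)]
        )
        chains["bulge_lower"] = np.column_stack(
            [x, y_low + 2 * sc + 1 * sc * bump + a3[3] * xi**3,
             np.full(L, zeye - 0.3 * sc)]
        )
        template_e = np.vstack([chains[k] for k in CHAIN_ORDER])
        n_d = template_e.shape[0]

        def y_only(per_chain_coeffs):
            """Displacement field acting on y only, cubic in xi per chain."""
            fld = np.zeros((n_d, 3))
            for ci, coeffs in enumerate(per_chain_coeffs):
                ys_ = np.polyval(coeffs, xi)
                fld[ci * L : (ci + 1) * L, 1] = ys_
            return fld.ravel()

        shape_basis = np.stack(
            [
                y_only(rng.normal(0, 0.5 * sc, size=(4, 4)))
                for _ in range(spec.n_eyelid_shape)
            ]
        )
        closure = np.zeros((4, 4))
        closure[CHAIN_ORDER.index("double_fold"), :] = [0, -3.5 * sc, 0, 3.5 * sc]
        closure[CHAIN_ORDER.index("upper_eyelid"), :] = [0, -5 * sc, 0, 5 * sc]
        closure[CHAIN_ORDER.index("lower_eyelid"), :] = [0, 1.5 * sc, 0, -1.5 * sc]
        # rows above are polyval coeffs (c3, c2, c1, c0): amp*(1 - xi^2)
        fold_shift = np.zeros((4, 4))
        fold_shift[CHAIN_ORDER.index("double_fold"), :] = [0, 2 * sc, 0, -2 * sc]
        fold_shift[CHAIN_ORDER.index("upper_eyelid"), :] = [0, 0.5 * sc, 0, -0.5 * sc]
        fold_shift[CHAIN_ORDER.index("bulge_lower"), :] = [0, -0.5 * sc, 0, 0.5 * sc]
        motion_fields = [closure, fold_shift]
        motion_basis = np.stack(
            [
                y_only(motion_fields[m] + rng.normal(0, 0.1 * sc, size=(4, 4)))
                for m in range(spec.n_eyelid_motion)
            ]
        )

        e_tris = []
        pairs = [(0, 1), (1, 2), (2, 3)]  # fold-upper, upper-lower, lower-bulge
        for c0, c1 in pairs:
            for i in range(L - 1):
                a = c0 * L + i
                b = c1 * L + i
                e_tris.append([a, a + 1, b])
                e_tris.append([a + 1, b + 1, b])
        eyelid_models[eye] = EyelidModel(
            template_e.ravel(), shape_basis, motion_basis, np.asarray(e_tris)
        )
        c_eyelid[eye] = {
            "upper": np.arange(L, 2 * L),
            "lower": np.arange(2 * L, 3 * L),
        }
        c_semantic[eye] = {
            label: np.arange(ci * L, (ci + 1) * L)
            for ci, label in enumerate(CHAIN_ORDER)
        }
        eyelid_brow_region[eye] = np.arange(0, L)  # the fold chain

    n_ball = spec.n_lat * spec.n_lon + 2 + spec.n_iris
    ring = np.arange(spec.n_lat * spec.n_lon + 2, n_ball)
    c_iris = {eye: ring.copy() for eye in EYES}

    cmap = CorrespondenceMap(
        face=c_face,
        eyelid=c_eyelid,
        iris=c_iris,
        semantic=c_semantic,
        face_eye_region=face_eye_region,
        face_brow_region=face_brow_region,
        eyelid_brow_region=eyelid_brow_region,
    )
    cmap.validate(n_face, 4 * L, n_ball)
    sample_idx = np.linspace(0, L - 1, spec.n_sparse).round().astype(int)
    return Assets(
        face_model=face_model,
        eyelid_models=eyelid_models,
        cmap=cmap,
        n_lat=spec.n_lat,
        n_lon=spec.n_lon,
        n_iris=spec.n_iris,
        eyelid_sample_idx=sample_idx,
        metadata={"seed": spec.seed, "scale": spec.scale, "units": "model",
                  "convention": "y-down-z-forward"},
    )


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectorySpec:
    """Ground-truth parameter trajectory for a synthetic sequence."""

    n_frames: int = 90
    motif: str = "fixation"
    params: dict = field(default_factory=dict)
    fps: float = 30.0
    noise_sigma: float = 0.0  # pixels, i.i.d. Gaussian per coordinate
    occlusions: List[dict] = field(default_factory=list)
    # each occlusion: {"start", "stop", "kind": face|eyelid|iris|semantic,
    #                  "eye": left|right|both}
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}; choose from {MOTIFS}")


def _motif_defaults(motif: str) -> dict:
    return {
        "fixation": {},
        "gaze_sweep": {"amplitude_deg": 20.0},
        "strabismus": {"offset_deg": 10.0, "eye": "right", "onset": 5, "ramp": 10},
        "ptosis": {"amplitude": 0.8, "eye": "right", "onset": 10, "ramp": 20},
        "nystagmus": {"amplitude_deg": 5.0, "frequency_hz": 3.0},
        "blink": {"amplitude": 1.2, "onset": 30, "width": 12},
    }[motif]


def _gaze_tracks(traj: TrajectorySpec) -> Dict[str, np.ndarray]:
    """Per-eye (theta, phi) in radians, shape (n_frames, 2)."""
    n = traj.n_frames
    p = {**_motif_defaults(traj.motif), **traj.params}
    tracks = {eye: np.zeros((n, 2)) for eye in EYES}
    t = np.arange(n)
    if traj.motif == "gaze_sweep":
        A = np.deg2rad(p["amplitude_deg"])
        q = n // 4 or 1
        tri = np.interp(t, [0, q, 3 * q, n - 1], [0, 1, -1, 0])
        for eye in EYES:
            tracks[eye][:, 0] = A * tri
    elif traj.motif == "strabismus":
        A = np.deg2rad(p["offset_deg"])
        ramp = np.clip((t - p["onset"]) / max(p["ramp"], 1), 0, 1)
        tracks[p["eye"]][:, 1] = A * ramp
    elif traj.motif == "nystagmus":
        A = np.deg2rad(p["amplitude_deg"])
        for eye in EYES:
            tracks[eye][:, 0] = A * np.sin(2 * np.pi * p["frequency_hz"] * t / traj.fps)
    return tracks


def _eyelid_tracks(traj: TrajectorySpec) -> Dict[str, np.ndarray]:
    """Per-eye eyelid motion weights, shape (n_frames, 2)."""
    n = traj.n_frames
    p = {**_motif_defaults(traj.motif), **traj.params}
    tracks = {eye: np.zeros((n, 2)) for eye in EYES}
    t = np.arange(n)
    if traj.motif == "ptosis":
        ramp = np.clip((t - p["onset"]) / max(p["ramp"], 1), 0, 1)
        tracks[p["eye"]][:, 0] = p["amplitude"] * ramp
    elif traj.motif == "blink":
        phase = np.clip((t - p["onset"]) / max(p["width"], 1), 0, 1)
        bump = 0.5 * (1 - np.cos(2 * np.pi * phase))
        for eye in EYES:
            tracks[eye][:, 0] = p["amplitude"] * bump
    return tracks


@dataclass
class SyntheticSequence:
    observations: List[FrameObservation]
    truth: List[FitState]
    assets: Assets
    camera: Camera
    spec: TrajectorySpec


def _occluded(traj: TrajectorySpec, frame: int, kind: str, eye: str) -> bool:
    for occ in traj.occlusions:
        if not occ["start"] <= frame < occ["stop"]:
            continue
        if occ["kind"] != kind:
            continue
        if occ.get("eye", "both") in (eye, "both"):
            return True
    return False


def generate_sequence(
    assets: Assets,
    traj: Optional[TrajectorySpec] = None,
    camera: Optional[Camera] = None,
    priors: Optional[PriorConfig] = None,
) -> SyntheticSequence:
    """Synthesize a feature stream plus its ground-truth state stream.

    Observations are exact projections of the ground-truth models with
    i.i.d. Gaussian pixel noise of ``traj.noise_sigma`` added to every
    coordinate; the occlusion schedule flips visibility flags (iris,
    eyelid, face landmarks) or removes semantic lines.
    """
    traj = traj or TrajectorySpec()
    camera = camera or Camera()
    priors = priors or PriorConfig()
    rng = np.random.default_rng(traj.seed)
    fm = assets.face_model
    image_size = (
        int(2 * camera.principal[0]),
        int(2 * camera.principal[1]),
    )

    wfs = np.concatenate([[1.0], 0.4 * rng.standard_normal(fm.n_shape - 1)])
    wfm_const = np.concatenate([[1.0], 0.2 * rng.standard_normal(fm.n_motion - 1)])
    wes = {eye: 0.5 * rng.standard_normal(assets.eyelid_models[eye].n_shape)
           for eye in EYES}
    pose = RigidPose(np.eye(3), np.array([0.0, 0.0, 600.0]))

    gaze = _gaze_tracks(traj)
    lids = _eyelid_tracks(traj)

    face0 = reconstruct_face(fm, FaceParams(wfs, wfm_const))
    rp = prior_radius_and_position(face0, assets.cmap, priors)
    statics = {}
    meshes = {}
    for eye in EYES:
        r_e, p_e = rp[eye]
        r_i = priors.iris_ratio * r_e
        statics[eye] = EyeballStatics(r_e, r_i, p_e)
        meshes[eye] = eyeball_mesh(
            EyeballModel(r_e, r_i, p_e, assets.n_lat, assets.n_lon, assets.n_iris)
        ).vertices

    def noisy(pts):
        pts = np.asarray(pts, float)
        if traj.noise_sigma > 0:
            return pts + rng.normal(0.0, traj.noise_sigma, size=pts.shape)
        return pts.copy()

    observations, truth = [], []
    for k in range(traj.n_frames):
        wfm = wfm_const.copy()
        face = reconstruct_face(fm, FaceParams(wfs, wfm))
        face_px = camera.project(apply_pose(face[assets.cmap.face], pose))
        face_vis = np.ones(face_px.shape[0], dtype=bool)
        if _occluded(traj, k, "face", "both"):
            face_vis[:] = False

        eyelid_obs = {}
        semantic_obs = {}
        iris_obs = {}
        eyelid_params = {}
        gaze_params = {}
        for eye in EYES:
            em = assets.eyelid_models[eye]
            wem = lids[eye][k]
            eyelid_params[eye] = EyelidParams(wes[eye].copy(), wem.copy())
            verts = reconstruct_eyelid(em, eyelid_params[eye])
            chain_px = camera.project(apply_pose(verts, pose))
            lid_sets = {}
            for lid in ("upper", "lower"):
                idx = assets.cmap.eyelid[eye][lid][assets.eyelid_sample_idx]
                vis = np.ones(len(idx), dtype=bool)
                if _occluded(traj, k, "eyelid", eye):
                    vis[:] = False
                lid_sets[lid] = LandmarkSet2D("eyelid", noisy(chain_px[idx]), vis)
            eyelid_obs[eye] = lid_sets
            if not _occluded(traj, k, "semantic", eye):
                semantic_obs[eye] = SemanticLineSet(
                    {
                        label: noisy(chain_px[assets.cmap.semantic[eye][label]])
                        for label in SEMANTIC_LABELS
                    }
                )
            th, ph = gaze[eye][k]
            gaze_params[eye] = EyeballRotation(float(th), float(ph))
            rot = eyeball_rotation_matrix(gaze_params[eye])
            ball = (meshes[eye] @ rot.T) + statics[eye].p_e
            ball_px = camera.project(apply_pose(ball, pose))
            iris_pts = ball_px[assets.cmap.iris[eye]]
            vis = np.ones(len(iris_pts), dtype=bool)
            if _occluded(traj, k, "iris", eye):
                vis[:] = False
            iris_obs[eye] = LandmarkSet2D("iris", noisy(iris_pts), vis)

        observations.append(
            FrameObservation(
                frame=k,
                image_size=image_size,
                face=LandmarkSet2D("face", noisy(face_px), face_vis),
                eyelid=eyelid_obs,
                iris=iris_obs,
                semantic_lines=semantic_obs,
            )
        )
        truth.append(
            FitState(
                frame=k,
                face=FaceParams(wfs.copy(), wfm),
                pose=RigidPose(pose.rotation.copy(), pose.translation.copy()),
                eyelid=eyelid_params,
                gaze=gaze_params,
                statics={eye: EyeballStatics(s.r_e, s.r_i, s.p_e.copy())
                         for eye, s in statics.items()},
            )
        )
    return SyntheticSequence(observations, truth, assets, camera, traj)
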