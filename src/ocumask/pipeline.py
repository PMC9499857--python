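"""Sequence tracking: run the three fitting stages over a feature stream."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .config import PriorConfig, SmoothingConfig
from .features import EYES, FrameObservation
from .fitting import (
    estimate_eyeball_statics,
    fit_eyeball_frame,
    fit_eyelid_first_frame,
    fit_eyelid_frame,
    fit_face_first_frame,
    fit_face_frame,
)
from .models import (
    Camera,
    EyeballModel,
    apply_pose,
    eyeball_mesh,
    eyeball_rotation_matrix,
    reconstruct_eyelid,
    reconstruct_face,
)
from .solver import SolverConfig
from .state import FitState
from .synthetic import Assets


@dataclass
class SequenceFitResult:
    states: List[FitState]
    reports: List[dict]  # per frame: stage -> StageFit

    def __len__(self):
        return len(self.states)


def fit_sequence(
    observations: List[FrameObservation],
    assets: Assets,
    camera: Optional[Camera] = None,
    solver: Optional[SolverConfig] = None,
    smoothing: Optional[SmoothingConfig] = None,
    priors: Optional[PriorConfig] = None,
) -> SequenceFitResult:
    """Fit every frame of a stream in order face -> eyelid -> eyeball.

    Frame 0 additionally estimates the static parameters (face shape
    weights, eyelid shape weights, eyeball radii/positions), which are then
    frozen; later frames track the dynamics with temporal smoothing and
    initialise each stage at the previous frame's solution.
    """
    camera = camera or Camera()
    solver = solver or SolverConfig()
    smoothing = smoothing if smoothing is not None else SmoothingConfig()
    priors = priors or PriorConfig()
    states: List[FitState] = []
    reports: List[dict] = []
    ball_vertices = {}
    prev: Optional[FitState] = None
    for obs in observations:
        frame_report = {}
        if prev is None:
            fparams, pose, sf = fit_face_first_frame(
                obs, assets.face_model, camera, assets.cmap, solver
            )
            frame_report["face"] = sf
            eyelid = {}
            for eye in EYES:
                eyelid[eye], sf_e = fit_eyelid_first_frame(
                    obs, pose, assets.eyelid_models[eye], camera, assets.cmap,
                    eye, solver,
                )
                frame_report[f"eyelid_{eye}"] = sf_e
            face_vertices = reconstruct_face(assets.face_model, fparams)
            statics = estimate_eyeball_statics(
                obs, face_vertices, pose, camera, assets.cmap, priors
            )
            gaze = {}
            for eye in EYES:
                ball_vertices[eye] = eyeball_mesh(
                    EyeballModel(
                        statics[eye].r_e, statics[eye].r_i, statics[eye].p_e,
                        assets.n_lat, assets.n_lon, assets.n_iris,
                    )
                ).vertices
                gaze[eye], sf_b = fit_eyeball_frame(
                    obs, statics[eye], pose, camera, assets.cmap, eye,
                    prev_gaze=None, smoothing=None, solver=solver,
                    ball_vertices=ball_vertices[eye],
                )
                frame_report[f"eyeball_{eye}"] = sf_b
        else:
            fparams, pose, sf = fit_face_frame(
                obs, prev, assets.face_model, camera, assets.cmap, smoothing, solver
            )
            frame_report["face"] = sf
            eyelid = {}
            for eye in EYES:
                eyelid[eye], sf_e = fit_eyelid_frame(
                    obs, prev, pose, assets.eyelid_models[eye], camera,
                    assets.cmap, eye, smoothing, solver,
                )
                frame_report[f"eyelid_{eye}"] = sf_e
            statics = prev.statics
            gaze = {}
            for eye in EYES:
                gaze[eye], sf_b = fit_eyeball_frame(
                    obs, statics[eye], pose, camera, assets.cmap, eye,
                    prev_gaze=prev.gaze[eye], smoothing=smoothing, solver=solver,
                    ball_vertices=ball_vertices[eye],
                )
                frame_report[f"eyeball_{eye}"] = sf_b
        prev = FitState(
            frame=obs.frame, face=fparams, pose=pose, eyelid=eyelid,
            gaze=gaze, statics=statics,
        )
        states.append(prev)
        reports.append(frame_report)
    return SequenceFitResult(states, reports)


def project_state(
    state: FitState, assets: Assets, camera: Optional[Camera] = None
) -> Dict[str, np.ndarray]:
    """Project a fitted state's model points back onto the image.

    Returns projected pixel coordinates for the evaluation landmark sets:
    ``iris_<eye>`` (the iris-ring vertices) and ``eyelid_<eye>`` (all
    semantic-chain vertices in chain order), plus ``face``.
    """
    camera = camera or Camera()
    out = {}
    face = reconstruct_face(assets.face_model, state.face)
    out["face"] = camera.project(apply_pose(face[assets.cmap.face], state.pose))
    for eye in EYES:
        verts = reconstruct_eyelid(assets.eyelid_models[eye], state.eyelid[eye])
        out[f"eyelid_{eye}"] = camera.project(apply_pose(verts, state.pose))
        st = state.statics[eye]
        ball = eyeball_mesh(
            EyeballModel(st.r_e, st.r_i, st.p_e, assets.n_lat, assets.n_lon,
                         assets.n_iris)
        ).vertices
        rot = eyeball_rotation_matrix(state.gaze[eye])
        posed = (ball @ rot.T) + st.p_e
        out[f"iris_{eye}"] = camera.project(
            apply_pose(posed, state.pose)[assets.cmap.iris[eye]]
        )
    return out
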