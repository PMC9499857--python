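"""Reconstruction evaluation: normalized pixel error, MRE/ARE, heat-map table.

The reconstruction is scored in image space: for each evaluation landmark,
the pixel distance between the detected 2D landmark and the projection of
its corresponding reconstructed 3D point, normalized by the inter-eye pixel
distance of that frame so face size (camera distance) drops out.  The
maximum (MRE) and mean (ARE) of the normalized errors summarise a record
set; occluded (landmark, point) pairs are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .errors import ContractViolationError, InsufficientDataError
from .features import EYES, FrameObservation
from .pipeline import project_state
from .state import FitState
from .synthetic import Assets


@dataclass
class EyeCenters:
    """Per-frame eye centres (centroid of each eye's visible iris landmarks)."""

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self):
        self.left = np.asarray(self.left, float).reshape(2)
        self.right = np.asarray(self.right, float).reshape(2)

    @property
    def d_eye(self) -> float:
        return float(np.linalg.norm(self.left - self.right))


@dataclass
class ErrorRecord:
    frame: int
    landmark: int
    kind: str  # {"eyeball", "eyelid"}
    d_abs: Optional[float]  # pixels
    d_norm: Optional[float]  # fraction of inter-eye distance
    excluded: bool = False


def eye_centers_from_observation(obs: FrameObservation) -> EyeCenters:
    cents = {}
    for eye in EYES:
        pts = obs.iris[eye].visible_points
        if pts.shape[0] == 0:
            pts = obs.iris[eye].points  # fall back to all points if occluded
        cents[eye] = pts.mean(axis=0)
    return EyeCenters(cents["left"], cents["right"])


def normalized_errors(
    detected: np.ndarray,
    projected: np.ndarray,
    centers: EyeCenters,
    mask: Optional[np.ndarray] = None,
    kind: str = "eyelid",
    frame: int = 0,
    landmark_offset: int = 0,
) -> List[ErrorRecord]:
    """Per-landmark absolute and normalized pixel errors.

    ``mask`` marks visible pairs; masked-out pairs yield excluded records
    carrying no distance values.
    """
    detected = np.atleast_2d(np.asarray(detected, float))
    projected = np.atleast_2d(np.asarray(projected, float))
    if detected.shape != projected.shape:
        raise ContractViolationError("detected/projected point counts differ")
    d_eye = centers.d_eye
    if d_eye <= 0:
        raise ContractViolationError("coincident eye centers: D_eye = 0")
    if mask is None:
        mask = np.ones(detected.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    d_abs = np.linalg.norm(detected - projected, axis=1)
    records = []
    for i in range(detected.shape[0]):
        if mask[i]:
            records.append(
                ErrorRecord(frame, landmark_offset + i, kind,
                            float(d_abs[i]), float(d_abs[i] / d_eye))
            )
        else:
            records.append(
                ErrorRecord(frame, landmark_offset + i, kind, None, None, True)
            )
    return records


def mre_are(records: List[ErrorRecord]):
    """Maximum and average normalized error over non-excluded records."""
    vals = [r.d_norm for r in records if not r.excluded]
    if not vals:
        raise InsufficientDataError("all records excluded; MRE/ARE undefined")
    return float(np.max(vals)), float(np.mean(vals))


def error_heatmap_table(
    records: List[ErrorRecord], n_frames: int, n_landmarks: int
) -> pd.DataFrame:
    """Frames x landmarks table of normalized errors (NaN where excluded)."""
    mat = np.full((n_frames, n_landmarks), np.nan)
    seen = set()
    for r in records:
        if not (0 <= r.frame < n_frames and 0 <= r.landmark < n_landmarks):
            raise ContractViolationError(
                f"record ({r.frame}, {r.landmark}) out of bounds"
            )
        if (r.frame, r.landmark) in seen:
            raise ContractViolationError(
                f"duplicate record for (frame, landmark) = ({r.frame}, {r.landmark})"
            )
        seen.add((r.frame, r.landmark))
        if not r.excluded:
            mat[r.frame, r.landmark] = r.d_norm
    return pd.DataFrame(
        mat,
        index=pd.RangeIndex(n_frames, name="frame"),
        columns=pd.RangeIndex(n_landmarks, name="landmark"),
    )


def save_heatmap(df: pd.DataFrame, path) -> None:
    """Write the heat-map table with full float precision (lossless round trip)."""
    df.to_csv(path, float_format="%.17g")


def evaluate_sequence(
    observations: List[FrameObservation],
    states: List[FitState],
    assets: Assets,
    camera=None,
) -> List[ErrorRecord]:
    """Score a fitted sequence against its detected landmarks.

    Eyeball records compare the detected iris landmarks with the projected
    iris-ring vertices (left eye first); eyelid records compare the detected
    semantic-line points with the projected chain vertices, in chain order
    (fold, upper, lower, bulge per eye).  Landmark indices run over
    kind-specific columns so the heat-map layout matches the evaluation
    granularity (2 x n_iris eyeball columns, 2 x 4 x chain eyelid columns).
    """
    from .features import SEMANTIC_LABELS

    records: List[ErrorRecord] = []
    for obs, state in zip(observations, states):
        proj = project_state(state, assets, camera)
        centers = eye_centers_from_observation(obs)
        off = 0
        for eye in EYES:
            lm = obs.iris[eye]
            records += normalized_errors(
                lm.points, proj[f"iris_{eye}"], centers, lm.visibility,
                kind="eyeball", frame=obs.frame, landmark_offset=off,
            )
            off += len(lm)
        off = 0
        for eye in EYES:
            for label in SEMANTIC_LABELS:
                idx = assets.cmap.semantic[eye][label]
                if eye in obs.semantic_lines and label in obs.semantic_lines[eye]:
                    det = obs.semantic_lines[eye][label]
                    mask = np.ones(len(idx), dtype=bool)
                else:
                    det = np.zeros((len(idx), 2))
                    mask = np.zeros(len(idx), dtype=bool)
                records += normalized_errors(
                    det, proj[f"eyelid_{eye}"][idx], centers, mask,
                    kind="eyelid", frame=obs.frame, landmark_offset=off,
                )
                off += len(idx)
    return records


def records_frame(records: List[ErrorRecord]) -> pd.DataFrame:
    """Record list as a tidy DataFrame (one row per (frame, landmark))."""
    return pd.DataFrame(
        {
            "frame": [r.frame for r in records],
            "landmark": [r.landmark for r in records],
            "kind": [r.kind for r in records],
            "d_abs": [r.d_abs for r in records],
            "d_norm": [r.d_norm for r in records],
            "excluded": [r.excluded for r in records],
        }
    )


def summarize(records: List[ErrorRecord]) -> pd.DataFrame:
    """Per-kind ARE/MRE summary with record counts."""
    rows = []
    for kind in ("eyeball", "eyelid"):
        sub = [r for r in records if r.kind == kind]
        if not sub:
            continue
        kept = [r for r in sub if not r.excluded]
        mre, are = mre_are(sub)
        rows.append(
            {"kind": kind, "ARE": are, "MRE": mre,
             "n_records": len(kept), "n_excluded": len(sub) - len(kept)}
        )
    return pd.DataFrame(rows)
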