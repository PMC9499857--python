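"""Readers and writers for the interchange formats.

Frame feature streams are JSON-lines (one frame per line) with a flat CSV
fallback for landmarks-only streams; model assets travel in a single NPZ
archive with a JSON metadata entry; fitted parameter sequences are wide CSV
tables; meshes are Wavefront OBJ or PLY (PLY via trimesh, with per-vertex
labels encoded as vertex colors).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import trimesh

from .errors import ContractViolationError, SchemaError
from .features import (
    EYES,
    LIDS,
    SEMANTIC_LABELS,
    CorrespondenceMap,
    FrameObservation,
    LandmarkSet2D,
    SemanticLineSet,
)
from .models import (
    EyeballRotation,
    EyelidModel,
    EyelidParams,
    FaceParams,
    ParametricFaceModel,
    RigidPose,
)
from .state import EyeballStatics, FitState
from .synthetic import Assets

# ---------------------------------------------------------------------------
# landmark streams


def _lm_to_json(lm: LandmarkSet2D) -> dict:
    return {"points": lm.points.tolist(), "visible": lm.visibility.tolist()}


def _lm_from_json(blob: dict, kind: str, line_no: int) -> LandmarkSet2D:
    try:
        return LandmarkSet2D(kind, np.asarray(blob["points"], float),
                             np.asarray(blob["visible"], bool))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"line {line_no}: bad {kind} landmark record: {exc}") from exc


def write_landmark_stream(observations: List[FrameObservation], path) -> None:
    with open(path, "w") as fh:
        for obs in observations:
            rec = {
                "frame": obs.frame,
                "image_size": list(obs.image_size),
                "face": _lm_to_json(obs.face),
                "eyelid": {
                    eye: {lid: _lm_to_json(obs.eyelid[eye][lid]) for lid in LIDS}
                    for eye in EYES
                },
                "iris": {eye: _lm_to_json(obs.iris[eye]) for eye in EYES},
                "semantic_lines": {
                    eye: {
                        label: obs.semantic_lines[eye][label].tolist()
                        for label in SEMANTIC_LABELS
                        if label in obs.semantic_lines[eye]
                    }
                    for eye in EYES
                    if eye in obs.semantic_lines
                },
            }
            fh.write(json.dumps(rec) + "\n")


def read_landmark_stream(path) -> List[FrameObservation]:
    """Read and validate a JSONL feature stream.

    Frames must be contiguous and ascending; schema violations report the
    offending line number and field.
    """
    observations = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"line {line_no}: invalid JSON: {exc}") from exc
            for key in ("frame", "image_size", "face", "eyelid", "iris"):
                if key not in rec:
                    raise SchemaError(f"line {line_no}: missing field {key!r}")
            frame = rec["frame"]
            expected = observations[-1].frame + 1 if observations else frame
            if frame != expected:
                raise SchemaError(
                    f"line {line_no}: frame index {frame} not contiguous "
                    f"(expected {expected})"
                )
            semantic = {}
            for eye, lines in rec.get("semantic_lines", {}).items():
                if lines:
                    semantic[eye] = SemanticLineSet(
                        {lab: np.asarray(pts, float) for lab, pts in lines.items()}
                    )
            observations.append(
                FrameObservation(
                    frame=frame,
                    image_size=tuple(rec["image_size"]),
                    face=_lm_from_json(rec["face"], "face", line_no),
                    eyelid={
                        eye: {
                            lid: _lm_from_json(rec["eyelid"][eye][lid], "eyelid", line_no)
                            for lid in LIDS
                        }
                        for eye in EYES
                    },
                    iris={
                        eye: _lm_from_json(rec["iris"][eye], "iris", line_no)
                        for eye in EYES
                    },
                    semantic_lines=semantic,
                )
            )
    return observations


def write_landmark_csv(observations: List[FrameObservation], path) -> None:
    """Flat CSV fallback: landmarks only (semantic lines are not representable)."""
    rows = []
    for obs in observations:
        for i, (p, v) in enumerate(zip(obs.face.points, obs.face.visibility)):
            rows.append((obs.frame, "face", "", "", i, p[0], p[1], bool(v)))
        for eye in EYES:
            for lid in LIDS:
                lm = obs.eyelid[eye][lid]
                for i, (p, v) in enumerate(zip(lm.points, lm.visibility)):
                    rows.append((obs.frame, "eyelid", eye, lid, i, p[0], p[1], bool(v)))
            lm = obs.iris[eye]
            for i, (p, v) in enumerate(zip(lm.points, lm.visibility)):
                rows.append((obs.frame, "iris", eye, "", i, p[0], p[1], bool(v)))
    df = pd.DataFrame(
        rows, columns=["frame", "kind", "eye", "part", "index", "x", "y", "visible"]
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_landmark_csv(path, image_size=(1920, 1080)) -> List[FrameObservation]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    observations = []
    for frame, grp in df.groupby("frame", sort=True):
        expected = observations[-1].frame + 1 if observations else frame
        if frame != expected:
            raise SchemaError(f"frame index {frame} not contiguous (expected {expected})")

        def build(kind, eye="", part=""):
            sub = grp[
                (grp["kind"] == kind) & (grp["eye"] == eye) & (grp["part"] == part)
            ].sort_values("index")
            return LandmarkSet2D(
                kind, sub[["x", "y"]].to_numpy(float),
                sub["visible"].astype(bool).to_numpy(),
            )

        observations.append(
            FrameObservation(
                frame=int(frame),
                image_size=tuple(image_size),
                face=build("face"),
                eyelid={eye: {lid: build("eyelid", eye, lid) for lid in LIDS}
                        for eye in EYES},
                iris={eye: build("iris", eye) for eye in EYES},
                semantic_lines={},
            )
        )
    return observations


# ---------------------------------------------------------------------------
# asset archive


def save_assets(assets: Assets, path) -> None:
    """Write an asset bundle to a single NPZ archive with JSON metadata."""
    arrays = {
        "core_tensor": assets.face_model.core_tensor,
        "face_topology": assets.face_model.topology,
        "face_landmark_map": assets.cmap.face,
        "eyelid_sample_idx": assets.eyelid_sample_idx,
        "sphere_dims": np.array([assets.n_lat, assets.n_lon, assets.n_iris]),
        "metadata_json": np.array(json.dumps(assets.metadata)),
    }
    for eye in EYES:
        em = assets.eyelid_models[eye]
        arrays[f"eyelid_{eye}_template"] = em.template
        arrays[f"eyelid_{eye}_shape_basis"] = em.shape_basis
        arrays[f"eyelid_{eye}_motion_basis"] = em.motion_basis
        arrays[f"eyelid_{eye}_topology"] = em.topology
        for lid in LIDS:
            arrays[f"eyelid_{eye}_map_{lid}"] = assets.cmap.eyelid[eye][lid]
        arrays[f"iris_{eye}_map"] = assets.cmap.iris[eye]
        for label in SEMANTIC_LABELS:
            arrays[f"semantic_{eye}_{label}"] = assets.cmap.semantic[eye][label]
        arrays[f"face_eye_region_{eye}"] = assets.cmap.face_eye_region[eye]
        arrays[f"face_brow_region_{eye}"] = assets.cmap.face_brow_region[eye]
        arrays[f"eyelid_brow_region_{eye}"] = assets.cmap.eyelid_brow_region[eye]
    np.savez(path, **arrays)


def load_assets(path) -> Assets:
    with np.load(path, allow_pickle=False) as z:
        face_model = ParametricFaceModel(z["core_tensor"], z["face_topology"])
        eyelid_models = {}
        c_eyelid, c_iris, c_sem = {}, {}, {}
        eye_reg, brow_reg, lid_brow = {}, {}, {}
        for eye in EYES:
            eyelid_models[eye] = EyelidModel(
                z[f"eyelid_{eye}_template"],
                z[f"eyelid_{eye}_shape_basis"],
                z[f"eyelid_{eye}_motion_basis"],
                z[f"eyelid_{eye}_topology"],
            )
            c_eyelid[eye] = {lid: z[f"eyelid_{eye}_map_{lid}"] for lid in LIDS}
            c_iris[eye] = z[f"iris_{eye}_map"]
            c_sem[eye] = {lab: z[f"semantic_{eye}_{lab}"] for lab in SEMANTIC_LABELS}
            eye_reg[eye] = z[f"face_eye_region_{eye}"]
            brow_reg[eye] = z[f"face_brow_region_{eye}"]
            lid_brow[eye] = z[f"eyelid_brow_region_{eye}"]
        cmap = CorrespondenceMap(
            face=z["face_landmark_map"], eyelid=c_eyelid, iris=c_iris,
            semantic=c_sem, face_eye_region=eye_reg, face_brow_region=brow_reg,
            eyelid_brow_region=lid_brow,
        )
        n_lat, n_lon, n_iris = (int(v) for v in z["sphere_dims"])
        metadata = json.loads(str(z["metadata_json"]))
        return Assets(
            face_model=face_model, eyelid_models=eyelid_models, cmap=cmap,
            n_lat=n_lat, n_lon=n_lon, n_iris=n_iris,
            eyelid_sample_idx=z["eyelid_sample_idx"], metadata=metadata,
        )


# ---------------------------------------------------------------------------
# fitted-state tables


def states_to_frame(states: List[FitState]) -> pd.DataFrame:
    """Wide per-frame parameter table (rotation as quaternion xyzw)."""
    from scipy.spatial.transform import Rotation

    rows = []
    for st in states:
        row = {"frame": st.frame}
        for i, v in enumerate(st.face.shape):
            row[f"wfs_{i}"] = v
        for i, v in enumerate(st.face.motion):
            row[f"wfm_{i}"] = v
        q = Rotation.from_matrix(st.pose.rotation).as_quat()
        for name, v in zip(("qx", "qy", "qz", "qw"), q):
            row[name] = v
        for name, v in zip(("tx", "ty", "tz"), st.pose.translation):
            row[name] = v
        for eye in EYES:
            for i, v in enumerate(st.eyelid[eye].shape):
                row[f"{eye}_wes_{i}"] = v
            for i, v in enumerate(st.eyelid[eye].motion):
                row[f"{eye}_wem_{i}"] = v
            row[f"{eye}_theta"] = st.gaze[eye].theta
            row[f"{eye}_phi"] = st.gaze[eye].phi
            s = st.statics[eye]
            row[f"{eye}_re"] = s.r_e
            row[f"{eye}_ri"] = s.r_i
            for name, v in zip(("pex", "pey", "pez"), s.p_e):
                row[f"{eye}_{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def save_states(states: List[FitState], path) -> None:
    states_to_frame(states).to_csv(path, index=False)


def load_states(path) -> List[FitState]:
    from scipy.spatial.transform import Rotation

    df = pd.read_csv(path)

    def vec(row, prefix):
        cols = sorted(
            (c for c in df.columns if c.startswith(prefix)),
            key=lambda c: int(c.rsplit("_", 1)[1]),
        )
        return np.array([row[c] for c in cols])

    states = []
    for _, row in df.iterrows():
        pose = RigidPose(
            Rotation.from_quat([row["qx"], row["qy"], row["qz"], row["qw"]]).as_matrix(),
            np.array([row["tx"], row["ty"], row["tz"]]),
        )
        eyelid, gaze, statics = {}, {}, {}
        for eye in EYES:
            eyelid[eye] = EyelidParams(vec(row, f"{eye}_wes_"), vec(row, f"{eye}_wem_"))
            gaze[eye] = EyeballRotation(row[f"{eye}_theta"], row[f"{eye}_phi"])
            statics[eye] = EyeballStatics(
                row[f"{eye}_re"], row[f"{eye}_ri"],
                np.array([row[f"{eye}_pex"], row[f"{eye}_pey"], row[f"{eye}_pez"]]),
            )
        states.append(
            FitState(
                frame=int(row["frame"]),
                face=FaceParams(vec(row, "wfs_"), vec(row, "wfm_")),
                pose=pose, eyelid=eyelid, gaze=gaze, statics=statics,
            )
        )
    return states


# ---------------------------------------------------------------------------
# meshes

_PALETTE = np.array(
    [
        [230, 25, 75, 255],
        [60, 180, 75, 255],
        [0, 130, 200, 255],
        [255, 225, 25, 255],
        [145, 30, 180, 255],
        [70, 240, 240, 255],
    ],
    dtype=np.uint8,
)


def write_mesh(vertices, topology, path, labels: Optional[np.ndarray] = None) -> None:
    """Write OBJ (plain text) or PLY (via trimesh; labels as vertex colors)."""
    vertices = np.atleast_2d(np.asarray(vertices, float))
    topology = np.asarray(topology, dtype=int)
    if topology.size and (topology.min() < 0 or topology.max() >= len(vertices)):
        raise ContractViolationError("topology indices out of range")
    path = Path(path)
    if path.suffix.lower() == ".obj":
        with open(path, "w") as fh:
            fh.write("# ocumask mesh\n")
            for v in vertices:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in topology:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    elif path.suffix.lower() == ".ply":
        mesh = trimesh.Trimesh(vertices=vertices, faces=topology, process=False)
        if labels is not None:
            labels = np.asarray(labels, dtype=int)
            if labels.shape[0] != len(vertices):
                raise ContractViolationError("one label per vertex required")
            mesh.visual.vertex_colors = _PALETTE[labels % len(_PALETTE)]
        mesh.export(path)
    else:
        raise ContractViolationError(f"unsupported mesh format {path.suffix!r}")


def read_mesh(path):
    """Read a mesh; returns (vertices, faces, labels-or-None)."""
    path = Path(path)
    mesh = trimesh.load(path, process=False, force="mesh")
    labels = None
    if path.suffix.lower() == ".ply" and mesh.visual.kind == "vertex":
        colors = np.asarray(mesh.visual.vertex_colors)[:, :4]
        labels = np.full(len(colors), -1)
        for li, col in enumerate(_PALETTE):
            labels[np.all(colors == col, axis=1)] = li
        if (labels < 0).all():
            labels = None
    return np.asarray(mesh.vertices), np.asarray(mesh.faces), labels
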