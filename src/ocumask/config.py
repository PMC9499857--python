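"""Run configuration: smoothing weights, eyeball priors, file loading.

Config files are TOML or YAML key/value tables with sections ``camera``,
``solver``, ``smoothing``, ``priors`` and a top-level ``seed``.  Every key
has a documented default; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from .errors import SchemaError
from .models import Camera
from .solver import SolverConfig


@dataclass
class SmoothingConfig:
    """Temporal smoothing weights (all >= 0; zero disables a term).

    Defaults are scaled to the typical residual magnitudes of the bundled
    synthetic asset; the energy forms, not the magnitudes, are what the
    method prescribes.
    """

    lambda_fm: float = 1e-2  # face motion weights
    lambda_R: float = 1e-3  # rotation (Frobenius norm on the matrix)
    lambda_t: float = 1e-3  # translation
    lambda_em: float = 1e-2  # eyelid motion weights
    lambda_theta: float = 1e-2  # gaze pitch
    lambda_phi: float = 1e-2  # gaze yaw

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise SchemaError(f"smoothing weight {f.name} must be >= 0")

    @classmethod
    def disabled(cls) -> "SmoothingConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class PriorConfig:
    """Prior convention for the static eyeball parameters.

    ``radius_ratio``: eyeball radius as a fraction of the distance between
    the two eye-region centroids of the fitted face.  ``depth_ratio``: the
    eyeball centre sits behind the eye-region centroid by this fraction of
    the eyeball radius (along +z, away from the camera).  ``iris_ratio`` is
    used only by the synthetic generator to pick a ground-truth iris radius;
    the estimator recovers the iris radius from the image.
    """

    radius_ratio: float = 0.2
    depth_ratio: float = 0.5
    iris_ratio: float = 0.5


@dataclass
class RunConfig:
    camera: Camera = field(default_factory=Camera)
    solver: SolverConfig = field(default_factory=SolverConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    seed: int = 0

    def provenance(self) -> dict:
        from . import __version__

        return {"tool_version": __version__, "config_hash": self.hash()}

    def hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name)) for f in fields(o)}
            if isinstance(o, np.ndarray):
                return o.tolist()
            return o

        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build(cls, table: dict, section: str):
    names = {f.name for f in fields(cls)}
    unknown = set(table) - names
    if unknown:
        raise SchemaError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return cls(**table)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a .toml or .yaml/.yml file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(text)
    elif path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text) or {}
    else:
        raise SchemaError(f"unsupported config format: {path.suffix}")

    known = {"camera", "solver", "smoothing", "priors", "seed"}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown top-level config key(s): {sorted(unknown)}")
    return RunConfig(
        camera=_build(Camera, data.get("camera", {}), "camera"),
        solver=_build(SolverConfig, data.get("solver", {}), "solver"),
        smoothing=_build(SmoothingConfig, data.get("smoothing", {}), "smoothing"),
        priors=_build(PriorConfig, data.get("priors", {}), "priors"),
        seed=int(data.get("seed", 0)),
    )
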