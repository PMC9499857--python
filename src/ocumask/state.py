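"""Per-frame fit state and static eyeball parameters."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .models import EyeballRotation, EyelidParams, FaceParams, RigidPose


@dataclass
class EyeballStatics:
    """Static eyeball parameters, estimated once in the first frame.

    ``r_e``/``r_i`` are the eyeball and iris radii, ``p_e`` the eyeball
    centre in the face-local frame.  They are fixed for all later frames.
    """

    r_e: float
    r_i: float
    p_e: np.ndarray

    def __post_init__(self):
        self.p_e = np.asarray(self.p_e, dtype=float).reshape(3)


@dataclass
class FitState:
    """All recovered parameters of one frame.

    ``face.shape``, and ``statics`` are estimated at frame 0 only and carried
    unchanged through the rest of the sequence; the remaining entries are
    per-frame dynamics.
    """

    frame: int
    face: FaceParams
    pose: RigidPose
    eyelid: Dict[str, EyelidParams]
    gaze: Dict[str, EyeballRotation]
    statics: Dict[str, EyeballStatics] = field(default_factory=dict)
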