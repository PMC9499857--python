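"""2D features extracted from examination video frames.

The fitting pipeline never touches pixels: its inputs are per-frame 2D
features as produced by landmark/semantic-line detectors — face landmarks,
sparse eyelid landmarks (per lid), iris landmarks, and four labelled
polylines per eye ("semantic lines": double fold, upper eyelid, lower eyelid,
lower bulge boundary).  This module holds the containers plus the eyelid
curve machinery: sparse eyelid landmarks are summarised by a least-squares
cubic ``y = a x^3 + b x^2 + c x + d`` which is then resampled uniformly in x
into dense landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .errors import ContractViolationError, InsufficientDataError

SEMANTIC_LABELS = ("double_fold", "upper_eyelid", "lower_eyelid", "bulge_lower")
EYES = ("left", "right")
LIDS = ("upper", "lower")


@dataclass
class LandmarkSet2D:
    """2D landmarks of one kind with a per-point visibility mask.

    Points flagged invisible are excluded from every residual and every
    error statistic downstream (the occlusion rule).
    """

    kind: str  # {"face", "eyelid", "iris"}
    points: np.ndarray  # (n, 2) pixels
    visibility: np.ndarray = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.visibility is None:
            self.visibility = np.ones(self.points.shape[0], dtype=bool)
        else:
            self.visibility = np.asarray(self.visibility, dtype=bool).ravel()
        if self.visibility.shape[0] != self.points.shape[0]:
            raise ContractViolationError("visibility mask length mismatch")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def visible_points(self) -> np.ndarray:
        return self.points[self.visibility]


@dataclass
class CubicCurve:
    """``y = a x^3 + b x^2 + c x + d`` with a fit domain in pixel units."""

    coeffs: np.ndarray  # (a, b, c, d)
    domain: np.ndarray  # (x_min, x_max)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float).reshape(4)
        self.domain = np.asarray(self.domain, dtype=float).reshape(2)
        if not np.all(np.isfinite(self.coeffs)):
            raise ContractViolationError("non-finite cubic coefficients")

    def __call__(self, x):
        a, b, c, d = self.coeffs
        x = np.asarray(x, dtype=float)
        return ((a * x + b) * x + c) * x + d


@dataclass
class DenseEyelidLandmarks:
    """Uniform-in-x resampling of an eyelid curve."""

    points: np.ndarray  # (n, 2)
    source: str = ""

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] >= 2 and not np.all(np.diff(self.points[:, 0]) > 0):
            raise ContractViolationError("dense landmark x must be strictly increasing")


@dataclass
class SemanticLineSet:
    """The four labelled eyelid polylines of one eye."""

    lines: Dict[str, np.ndarray]

    def __post_init__(self):
        lines = {}
        for label, pts in self.lines.items():
            if label not in SEMANTIC_LABELS:
                raise ContractViolationError(f"unknown semantic line label {label!r}")
            pts = np.atleast_2d(np.asarray(pts, dtype=float))
            if pts.shape[0] < 2:
                raise ContractViolationError(f"semantic line {label!r} needs >= 2 points")
            lines[label] = pts
        self.lines = lines

    def __getitem__(self, label: str) -> np.ndarray:
        return self.lines[label]

    def __contains__(self, label: str) -> bool:
        return label in self.lines


@dataclass
class CorrespondenceMap:
    """Index maps tying 2D features to model vertices.

    ``face``: face-landmark index -> face vertex index.
    ``eyelid``: eye -> lid -> array mapping dense-landmark index -> eyelid
    vertex index.  ``iris``: eye -> iris-landmark index -> eyeball vertex
    index.  ``semantic``: eye -> line label -> eyelid vertex indices forming
    that line.  ``face_eye_region``: eye -> face vertex indices around the
    eye socket (used for the eyeball placement prior).  ``face_brow_region``
    and ``eyelid_brow_region`` designate the paired regions used by eyebrow
    deformation transfer.
    """

    face: np.ndarray
    eyelid: Dict[str, Dict[str, np.ndarray]]
    iris: Dict[str, np.ndarray]
    semantic: Dict[str, Dict[str, np.ndarray]]
    face_eye_region: Dict[str, np.ndarray] = field(default_factory=dict)
    face_brow_region: Dict[str, np.ndarray] = field(default_factory=dict)
    eyelid_brow_region: Dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self, n_face: int, n_eyelid: int, n_eyeball: int) -> None:
        if self.face.min() < 0 or self.face.max() >= n_face:
            raise ContractViolationError("face correspondence index out of range")
        for eye in self.eyelid:
            for lid, idx in self.eyelid[eye].items():
                if idx.min() < 0 or idx.max() >= n_eyelid:
                    raise ContractViolationError(
                        f"eyelid correspondence out of range ({eye}/{lid})"
                    )
        for eye, idx in self.iris.items():
            if idx.min() < 0 or idx.max() >= n_eyeball:
                raise ContractViolationError(f"iris correspondence out of range ({eye})")
        for eye in self.semantic:
            for label, idx in self.semantic[eye].items():
                if idx.min() < 0 or idx.max() >= n_eyelid:
                    raise ContractViolationError(
                        f"semantic vertex set out of range ({eye}/{label})"
                    )


@dataclass
class FrameObservation:
    """All 2D features of one video frame."""

    frame: int
    image_size: tuple  # (width, height) pixels
    face: LandmarkSet2D
    eyelid: Dict[str, Dict[str, LandmarkSet2D]]  # eye -> lid -> landmarks
    iris: Dict[str, LandmarkSet2D]  # eye -> landmarks
    semantic_lines: Dict[str, SemanticLineSet]  # eye -> lines


# ---------------------------------------------------------------------------
# operations


def fit_eyelid_curve(landmarks) -> CubicCurve:
    """Least-squares cubic through visible eyelid landmarks.

    Solves the Vandermonde system ``V [d c b a]' = y``.  With fewer than four
    distinct x values the polynomial degree degrades to (distinct - 1) so the
    system stays full rank; with fewer than two visible points there is
    nothing to fit.
    """
    if isinstance(landmarks, LandmarkSet2D):
        pts = landmarks.visible_points
    else:
        pts = np.atleast_2d(np.asarray(landmarks, dtype=float))
    if pts.shape[0] < 2:
        raise InsufficientDataError(
            f"eyelid curve fit needs >= 2 visible landmarks, got {pts.shape[0]}"
        )
    x, y = pts[:, 0], pts[:, 1]
    degree = min(3, len(np.unique(x)) - 1)
    V = np.vander(x, degree + 1, increasing=True)
    sol, *_ = np.linalg.lstsq(V, y, rcond=None)
    coeffs = np.zeros(4)
    coeffs[3 - degree :] = sol[::-1]  # store as (a, b, c, d)
    return CubicCurve(coeffs, (x.min(), x.max()))


def densify(curve: CubicCurve, n: int, source: str = "") -> DenseEyelidLandmarks:
    """Sample ``n`` points uniformly in x over the curve's fit domain."""
    if n < 2:
        raise ContractViolationError("densify needs n >= 2")
    x0, x1 = curve.domain
    if not x1 > x0:
        raise InsufficientDataError("empty curve domain")
    x = np.linspace(x0, x1, n)
    return DenseEyelidLandmarks(np.column_stack([x, curve(x)]), source=source)


def _segment_closest(point: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Closest points on segments [a_i, b_i] to ``point`` (vectorised)."""
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", point - a, ab) / np.where(denom == 0, 1.0, denom)
    t = np.clip(np.where(denom == 0, 0.0, t), 0.0, 1.0)
    return a + t[:, None] * ab


def polyline_closest_point(point, polyline) -> np.ndarray:
    """Closest point on a polyline (segment interiors and endpoints allowed)."""
    p = np.asarray(point, dtype=float).reshape(2)
    line = np.atleast_2d(np.asarray(polyline, dtype=float))
    if line.shape[0] < 2:
        raise ContractViolationError("polyline needs >= 2 points")
    cand = _segment_closest(p, line[:-1], line[1:])
    d2 = ((cand - p) ** 2).sum(axis=1)
    return cand[np.argmin(d2)]


def point_to_polyline_distance(point, polyline) -> float:
    """Minimum Euclidean distance from a point to a polyline."""
    p = np.asarray(point, dtype=float).reshape(2)
    q = polyline_closest_point(p, polyline)
    return float(np.hypot(*(p - q)))
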