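"""Parametric generative models for face, eyelids and eyeballs.

The de-identified output of the pipeline is a mesh sequence produced by three
generative models:

* a bilinear face model: a core tensor contracted with a shape weight vector
  and a motion weight vector gives the face vertices;
* a linear eyelid model: template plus shape- and motion-basis offsets;
* a spherical eyeball model: a sphere of radius ``r_e`` carrying an iris ring
  of planar radius ``r_i``, positioned at an offset ``p_e`` relative to the
  face and rotated by two gaze angles (pitch ``theta``, yaw ``phi``).

Coordinate conventions used throughout the package:

* model/world frame: x right, y **down**, z away from the camera (depth), so a
  face looking at the camera has its visible surface at smaller z;
* image frame: origin top-left, x right, y down, pixel units;
* eyeball local frame: the gaze axis is ``-z`` (toward the camera at identity
  pose); the iris ring lies at polar angle ``arcsin(r_i / r_e)`` from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ContractViolationError,
    DegenerateProjectionError,
    DimensionMismatchError,
)

_ORTHO_TOL = 1e-8


# ---------------------------------------------------------------------------
# face


@dataclass
class ParametricFaceModel:
    """Bilinear face model.

    Parameters
    ----------
    core_tensor : ndarray, shape (3 * n_vertices, n_shape, n_motion)
        Core tensor of stacked vertex coordinates; the first axis interleaves
        x, y, z per vertex.
    topology : ndarray, shape (n_triangles, 3)
        Triangle vertex indices.
    """

    core_tensor: np.ndarray
    topology: np.ndarray

    def __post_init__(self):
        self.core_tensor = np.asarray(self.core_tensor, dtype=float)
        self.topology = np.asarray(self.topology, dtype=int)
        if self.core_tensor.ndim != 3:
            raise DimensionMismatchError("core_tensor must be rank 3")
        if self.core_tensor.shape[0] % 3:
            raise DimensionMismatchError(
                "core_tensor first axis must be 3 * n_vertices"
            )
        nv = self.core_tensor.shape[0] // 3
        if self.topology.size and (
            self.topology.min() < 0 or self.topology.max() >= nv
        ):
            raise ContractViolationError("topology indices out of range")

    @property
    def n_vertices(self) -> int:
        return self.core_tensor.shape[0] // 3

    @property
    def n_shape(self) -> int:
        return self.core_tensor.shape[1]

    @property
    def n_motion(self) -> int:
        return self.core_tensor.shape[2]


@dataclass
class FaceParams:
    """Shape and motion weights of the bilinear face model.

    By package convention the leading entry of each weight vector is pinned to
    1 during fitting, which removes the bilinear scale ambiguity
    (``a * w_shape`` with ``w_motion / a`` generates the same face).
    """

    shape: np.ndarray
    motion: np.ndarray

    def __post_init__(self):
        self.shape = np.atleast_1d(np.asarray(self.shape, dtype=float))
        self.motion = np.atleast_1d(np.asarray(self.motion, dtype=float))


def reconstruct_face(model: ParametricFaceModel, params: FaceParams) -> np.ndarray:
    """Contract the core tensor with the weight vectors.

    Returns the face vertices as an ``(n_vertices, 3)`` array.  The output is
    bilinear: linear in the shape weights with motion held fixed and vice
    versa.
    """
    if params.shape.shape[0] != model.n_shape:
        raise DimensionMismatchError(
            f"shape weights have length {params.shape.shape[0]}, "
            f"model expects {model.n_shape} (shape axis)"
        )
    if params.motion.shape[0] != model.n_motion:
        raise DimensionMismatchError(
            f"motion weights have length {params.motion.shape[0]}, "
            f"model expects {model.n_motion} (motion axis)"
        )
    flat = np.einsum("ksm,s,m->k", model.core_tensor, params.shape, params.motion)
    return flat.reshape(-1, 3)


# ---------------------------------------------------------------------------
# eyelid


@dataclass
class EyelidModel:
    """Linear eyelid model: template plus shape and motion basis offsets."""

    template: np.ndarray  # (3 * n_vertices,)
    shape_basis: np.ndarray  # (n_shape, 3 * n_vertices)
    motion_basis: np.ndarray  # (n_motion, 3 * n_vertices)
    topology: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))

    def __post_init__(self):
        self.template = np.asarray(self.template, dtype=float).ravel()
        self.shape_basis = np.atleast_2d(np.asarray(self.shape_basis, dtype=float))
        self.motion_basis = np.atleast_2d(np.asarray(self.motion_basis, dtype=float))
        self.topology = np.asarray(self.topology, dtype=int)
        n = self.template.shape[0]
        if n % 3:
            raise DimensionMismatchError("template length must be 3 * n_vertices")
        for name, basis in (("shape", self.shape_basis), ("motion", self.motion_basis)):
            if basis.size and basis.shape[1] != n:
                raise DimensionMismatchError(
                    f"{name} basis rows have length {basis.shape[1]}, template {n}"
                )

    @property
    def n_vertices(self) -> int:
        return self.template.shape[0] // 3

    @property
    def n_shape(self) -> int:
        return self.shape_basis.shape[0]

    @property
    def n_motion(self) -> int:
        return self.motion_basis.shape[0]


@dataclass
class EyelidParams:
    shape: np.ndarray
    motion: np.ndarray

    def __post_init__(self):
        self.shape = np.atleast_1d(np.asarray(self.shape, dtype=float))
        self.motion = np.atleast_1d(np.asarray(self.motion, dtype=float))


def reconstruct_eyelid(model: EyelidModel, params: EyelidParams) -> np.ndarray:
    """Template + shape offsets + motion offsets, as ``(n_vertices, 3)``.

    Affine in ``(shape, motion)`` jointly.
    """
    if params.shape.shape[0] != model.n_shape:
        raise DimensionMismatchError(
            f"eyelid shape weights have length {params.shape.shape[0]}, "
            f"model expects {model.n_shape} (shape axis)"
        )
    if params.motion.shape[0] != model.n_motion:
        raise DimensionMismatchError(
            f"eyelid motion weights have length {params.motion.shape[0]}, "
            f"model expects {model.n_motion} (motion axis)"
        )
    flat = model.template.copy()
    if model.n_shape:
        flat = flat + params.shape @ model.shape_basis
    if model.n_motion:
        flat = flat + params.motion @ model.motion_basis
    return flat.reshape(-1, 3)


# ---------------------------------------------------------------------------
# eyeball


@dataclass
class EyeballModel:
    """Spherical eyeball with an iris ring.

    ``r_e`` is the eyeball radius, ``r_i`` the planar iris radius
    (``0 < r_i < r_e``) and ``p_e`` the eyeball-centre position relative to
    the face (face-local frame).  ``n_lat`` interior latitude rings of
    ``n_lon`` vertices each, two pole vertices and an explicitly indexed iris
    ring of ``n_iris`` vertices make up the tessellation.
    """

    r_e: float
    r_i: float
    p_e: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_lat: int = 7
    n_lon: int = 12
    n_iris: int = 19

    def __post_init__(self):
        self.p_e = np.asarray(self.p_e, dtype=float).reshape(3)
        if not (0 < self.r_i < self.r_e):
            raise ContractViolationError(
                f"require 0 < r_i < r_e, got r_i={self.r_i}, r_e={self.r_e}"
            )

    @property
    def n_vertices(self) -> int:
        return self.n_lat * self.n_lon + 2 + self.n_iris


@dataclass
class EyeballMesh:
    vertices: np.ndarray  # (n, 3), eyeball-local frame
    topology: np.ndarray  # (m, 3)
    iris_ring: np.ndarray  # indices of the iris-ring vertices


def eyeball_mesh(model: EyeballModel) -> EyeballMesh:
    """Tessellate the eyeball sphere in its local frame.

    The gaze axis is ``-z``; the iris ring is the circle where the sphere
    meets the cone of half-angle ``arcsin(r_i / r_e)`` about the gaze axis,
    i.e. it lies in the plane ``z = -sqrt(r_e^2 - r_i^2)``.
    """
    re_, ri = model.r_e, model.r_i
    # interior latitudes, measured as polar angle from the gaze axis (-z)
    polar = np.linspace(0.0, np.pi, model.n_lat + 2)[1:-1]
    lon = np.linspace(0.0, 2 * np.pi, model.n_lon, endpoint=False)
    a, b = np.meshgrid(polar, lon, indexing="ij")
    grid = re_ * np.stack(
        [np.sin(a) * np.cos(b), np.sin(a) * np.sin(b), -np.cos(a)], axis=-1
    ).reshape(-1, 3)
    poles = np.array([[0.0, 0.0, -re_], [0.0, 0.0, re_]])
    alpha = np.arcsin(ri / re_)
    ring_lon = np.linspace(0.0, 2 * np.pi, model.n_iris, endpoint=False)
    ring = re_ * np.stack(
        [
            np.sin(alpha) * np.cos(ring_lon),
            np.sin(alpha) * np.sin(ring_lon),
            -np.cos(alpha) * np.ones_like(ring_lon),
        ],
        axis=-1,
    )
    vertices = np.vstack([grid, poles, ring])
    iris_ring = np.arange(grid.shape[0] + 2, vertices.shape[0])

    tris = []
    nlon = model.n_lon
    front = grid.shape[0]  # index of front pole
    for j in range(nlon):  # pole caps
        tris.append([front, j, (j + 1) % nlon])
        base = (model.n_lat - 1) * nlon
        tris.append([front + 1, base + (j + 1) % nlon, base + j])
    for i in range(model.n_lat - 1):  # latitude strips
        for j in range(nlon):
            a0 = i * nlon + j
            a1 = i * nlon + (j + 1) % nlon
            b0 = (i + 1) * nlon + j
            b1 = (i + 1) * nlon + (j + 1) % nlon
            tris.append([a0, b0, a1])
            tris.append([a1, b0, b1])
    return EyeballMesh(vertices, np.asarray(tris, dtype=int), iris_ring)


@dataclass
class EyeballRotation:
    """Gaze angles in radians: ``theta`` pitch about x, ``phi`` yaw about y."""

    theta: float
    phi: float

    def __post_init__(self):
        if not (np.isfinite(self.theta) and np.isfinite(self.phi)):
            raise ContractViolationError("gaze angles must be finite")


def _rot_x(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def eyeball_rotation_matrix(rot: EyeballRotation) -> np.ndarray:
    """Convert gaze angles to a rotation matrix.

    Convention (fixed and shared with the synthetic generator): yaw about the
    vertical axis first, then pitch about the horizontal axis, i.e.
    ``R = Rx(theta) @ Ry(phi)``.  ``theta = phi = 0`` gives the identity.
    """
    return _rot_x(rot.theta) @ _rot_y(rot.phi)


# ---------------------------------------------------------------------------
# pose and camera


@dataclass
class RigidPose:
    """Rigid transform ``v -> R v + t`` with R in SO(3)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ContractViolationError(
                f"rotation is not orthonormal (max |R'R - I| = {err:.2e})"
            )
        if np.linalg.det(self.rotation) < 0:
            raise ContractViolationError("rotation has determinant -1")

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidPose":
        return RigidPose(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Return the pose equivalent to applying ``other`` first, then self."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def apply_pose(vertices: np.ndarray, pose: RigidPose) -> np.ndarray:
    """Apply ``v -> R v + t`` to an ``(n, 3)`` vertex array."""
    v = np.asarray(vertices, dtype=float)
    return v @ pose.rotation.T + pose.translation


@dataclass
class Camera:
    """Projection of 3D model-frame points onto the image.

    ``pinhole`` mode: ``(f x / z + cx, f y / z + cy)`` (requires z > 0);
    ``weak_perspective``: ``(s x + cx, s y + cy)``.
    """

    mode: str = "pinhole"
    focal: float = 3000.0
    principal: np.ndarray = field(default_factory=lambda: np.array([960.0, 540.0]))
    scale: float = 5.0

    def __post_init__(self):
        self.principal = np.asarray(self.principal, dtype=float).reshape(2)
        if self.mode not in ("pinhole", "weak_perspective"):
            raise ContractViolationError(f"unknown camera mode {self.mode!r}")
        if self.mode == "pinhole" and self.focal <= 0:
            raise ContractViolationError("pinhole focal length must be > 0")
        if self.mode == "weak_perspective" and self.scale <= 0:
            raise ContractViolationError("weak-perspective scale must be > 0")

    def project(self, points3d: np.ndarray) -> np.ndarray:
        return project(points3d, self)

    def jacobian(self, points3d: np.ndarray) -> np.ndarray:
        """Per-point 2x3 Jacobian of the projection, shape ``(n, 2, 3)``."""
        p = np.atleast_2d(np.asarray(points3d, dtype=float))
        n = p.shape[0]
        J = np.zeros((n, 2, 3))
        if self.mode == "pinhole":
            z = p[:, 2]
            J[:, 0, 0] = self.focal / z
            J[:, 1, 1] = self.focal / z
            J[:, 0, 2] = -self.focal * p[:, 0] / z**2
            J[:, 1, 2] = -self.focal * p[:, 1] / z**2
        else:
            J[:, 0, 0] = self.scale
            J[:, 1, 1] = self.scale
        return J


def project(points3d: np.ndarray, camera: Camera) -> np.ndarray:
    """Project ``(n, 3)`` model-frame points to ``(n, 2)`` pixel coordinates."""
    p = np.atleast_2d(np.asarray(points3d, dtype=float))
    if camera.mode == "pinhole":
        bad = np.flatnonzero(p[:, 2] <= 0)
        if bad.size:
            raise DegenerateProjectionError(bad)
        return p[:, :2] * (camera.focal / p[:, 2])[:, None] + camera.principal
    return p[:, :2] * camera.scale + camera.principal
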