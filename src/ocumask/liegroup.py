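"""SO(3) helpers: exponential map, right Jacobian, hat operator.

The fitting stages optimise rotation through a global axis-angle chart
``R(delta) = Exp(delta) @ R_ref`` anchored at the initial rotation; the
right Jacobian supplies exact derivatives of the chart away from the anchor,
so analytic Jacobians match finite differences at arbitrary ``delta``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def hat(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]], dtype=float)


def exp_so3(delta: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(np.asarray(delta, dtype=float)).as_matrix()


def log_so3(R: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(np.asarray(R, dtype=float)).as_rotvec()


def right_jacobian(delta: np.ndarray) -> np.ndarray:
    """Right Jacobian J_r of SO(3): d Exp(delta + d) ~ Exp(delta) Exp(J_r d)."""
    delta = np.asarray(delta, dtype=float)
    theta = np.linalg.norm(delta)
    K = hat(delta)
    if theta < 1e-8:
        return np.eye(3) - 0.5 * K + K @ K / 6.0
    return (
        np.eye(3)
        - (1 - np.cos(theta)) / theta**2 * K
        + (theta - np.sin(theta)) / theta**3 * (K @ K)
    )
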