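"""Deformation transfer for eyebrow motion.

The linear eyelid model has no eyebrow degrees of freedom; eyebrow motion
recovered by the face model is propagated onto the designated eyelid region
through Gaussian influence weights computed between two paired semantic
regions (one on the face mesh, one on the eyelid mesh).  All vertices are in
the face-local frame so global pose does not leak into the transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractViolationError


@dataclass
class TransferField:
    """Gaussian influence weights between a face region and an eyelid region.

    ``weights[i, j] = exp(-||v_f_i - v_e_j||^2 / (2 r^2))`` for face-region
    vertex i and eyelid-region vertex j; the neighbour set of every eyelid
    vertex is the whole face region (``n_neighbors = len(face_region)``).
    """

    face_region: np.ndarray
    eyelid_region: np.ndarray
    weights: np.ndarray  # (len(face_region), len(eyelid_region))
    radius: float

    @property
    def n_neighbors(self) -> int:
        return len(self.face_region)


def compute_transfer_field(
    face_vertices: np.ndarray,
    eyelid_vertices: np.ndarray,
    face_region: np.ndarray,
    eyelid_region: np.ndarray,
    radius: float,
) -> TransferField:
    """Evaluate the Gaussian influence weights for the paired regions."""
    face_region = np.asarray(face_region, dtype=int)
    eyelid_region = np.asarray(eyelid_region, dtype=int)
    if face_region.size == 0 or eyelid_region.size == 0:
        raise ContractViolationError("transfer regions must be non-empty")
    if radius <= 0:
        raise ContractViolationError("influence radius must be > 0")
    vf = np.asarray(face_vertices, float)[face_region]  # (nf, 3)
    ve = np.asarray(eyelid_vertices, float)[eyelid_region]  # (ne, 3)
    d2 = ((vf[:, None, :] - ve[None, :, :]) ** 2).sum(axis=2)
    return TransferField(face_region, eyelid_region, np.exp(-d2 / (2 * radius**2)), radius)


def transfer_eyebrow_motion(
    field: TransferField,
    face_prev: np.ndarray,
    face_cur: np.ndarray,
    eyelid_prev: np.ndarray,
) -> np.ndarray:
    """Advance the eyelid-region vertices with the face-region motion.

    ``v_e_j(t) = v_e_j(t-1) + sum_i w_ij / N * (v_f_i(t) - v_f_i(t-1))``
    over the face-region neighbours i.  Returns a full copy of the eyelid
    vertex array with the region rows updated.
    """
    face_prev = np.asarray(face_prev, float)
    face_cur = np.asarray(face_cur, float)
    if face_prev.shape != face_cur.shape:
        raise ContractViolationError("face vertex arrays must have matching shapes")
    motion = face_cur[field.face_region] - face_prev[field.face_region]  # (nf, 3)
    out = np.asarray(eyelid_prev, float).copy()
    out[field.eyelid_region] += (field.weights.T @ motion) / field.n_neighbors
    return out
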