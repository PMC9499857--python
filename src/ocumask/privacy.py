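"""Face-verification and identification metrics over similarity scores.

The de-identification claim is audited by attacking the masked images with
external face-recognition systems; those systems' raw similarity scores
(query x gallery) are the input here.  This module computes the standard
verification metrics: TAR/FAR at a threshold, the ROC curve with trapezoidal
AUC, TAR at fixed FAR operating points, and Rank-1 identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from .errors import ContractViolationError, InsufficientDataError


@dataclass
class ScoreMatrix:
    """Similarity scores between query and gallery images (larger = more similar)."""

    scores: np.ndarray  # (Q, G)
    query_ids: Sequence
    gallery_ids: Sequence

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.query_ids = list(self.query_ids)
        self.gallery_ids = list(self.gallery_ids)
        q, g = self.scores.shape
        if len(self.query_ids) != q or len(self.gallery_ids) != g:
            raise ContractViolationError("identity label lengths do not match scores")
        if not np.all(np.isfinite(self.scores)):
            raise ContractViolationError("scores must be finite")

    @property
    def genuine_mask(self) -> np.ndarray:
        qa = np.asarray(self.query_ids, dtype=object)
        ga = np.asarray(self.gallery_ids, dtype=object)
        return qa[:, None] == ga[None, :]


@dataclass
class VerificationOutcome:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tar(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def far(self) -> float:
        return self.fp / (self.fp + self.tn)


def tar_far_at_threshold(scores: ScoreMatrix, threshold: float) -> VerificationOutcome:
    """Accept a (query, gallery) pair iff score >= threshold.

    TAR = TP / (TP + FN) over genuine pairs; FAR = FP / (FP + TN) over
    impostor pairs.
    """
    if scores.scores.size == 0:
        raise InsufficientDataError("empty score matrix")
    genuine = scores.genuine_mask
    accept = scores.scores >= threshold
    tp = int(np.sum(accept & genuine))
    fn = int(np.sum(~accept & genuine))
    fp = int(np.sum(accept & ~genuine))
    tn = int(np.sum(~accept & ~genuine))
    return VerificationOutcome(threshold, tp, fp, tn, fn)


@dataclass
class RocResult:
    points: np.ndarray  # (n, 2) columns (FAR, TAR), sorted by FAR
    thresholds: np.ndarray
    auc: float
    tar_at_far: Dict[float, float] = field(default_factory=dict)


def roc_curve(
    scores: ScoreMatrix, far_levels: Tuple[float, ...] = (0.1, 0.01)
) -> RocResult:
    """ROC over thresholds at every distinct score plus +/- infinity.

    AUC by trapezoidal integration; TAR@FAR=x reported at the strictest
    threshold whose FAR does not exceed x (step-function semantics, no
    interpolation).
    """
    genuine = scores.genuine_mask
    s = scores.scores
    n_gen = int(genuine.sum())
    n_imp = int((~genuine).sum())
    if n_gen == 0 or n_imp == 0:
        raise InsufficientDataError("need at least one genuine and one impostor pair")
    thresholds = np.concatenate(
        [[np.inf], np.unique(s)[::-1], [-np.inf]]
    )
    gen_scores = np.sort(s[genuine])
    imp_scores = np.sort(s[~genuine])
    # accepted counts = #scores >= threshold
    tar = 1.0 - np.searchsorted(gen_scores, thresholds, side="left") / n_gen
    far = 1.0 - np.searchsorted(imp_scores, thresholds, side="left") / n_imp
    order = np.argsort(far, kind="stable")
    pts = np.column_stack([far[order], tar[order]])
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    tar_at = {}
    for level in far_levels:
        ok = far <= level
        tar_at[level] = float(tar[ok].max()) if ok.any() else 0.0
    return RocResult(pts, thresholds[order], auc, tar_at)


def rank1(scores: ScoreMatrix, tie_is_failure: bool = True) -> float:
    """Fraction of queries whose single best gallery match shares their identity.

    A tie for the best score counts as failure by default (conservative for
    a privacy claim: an attacker who must pick one of several equal-best
    candidates is not credited with success).
    """
    gallery = np.asarray(scores.gallery_ids, dtype=object)
    hits = 0
    for qi, qid in enumerate(scores.query_ids):
        if qid not in scores.gallery_ids:
            raise ContractViolationError(
                f"query identity {qid!r} absent from gallery"
            )
        row = scores.scores[qi]
        best_idx = np.flatnonzero(row == row.max())
        if tie_is_failure:
            if len(best_idx) == 1 and gallery[best_idx[0]] == qid:
                hits += 1
        elif any(gallery[b] == qid for b in best_idx):
            hits += 1
    return hits / scores.scores.shape[0]
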