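"""Similarity (7-parameter) Procrustes alignment and cohort averaging.

Corresponded subjects are aligned in their original millimetre space with
the closed-form weighted similarity Procrustes solution (3 translations +
3 rotations + 1 uniform scale; reflections refused), iterated against the
evolving mean (generalized Procrustes).  Filler vertices get zero weight
so synthesized hole patches never steer the alignment.  The average model
carries the per-vertex mean position, a scalar per-vertex variance (mean
squared deviation of aligned subjects about the mean, mm^2), the mean
colour over non-filler contributions, and the per-vertex filler fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .registration import CorrespondedCohort


class AlignmentError(RuntimeError):
    pass


@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation (7 parameters)."""

    scale: float
    rotation: np.ndarray  # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.scale * x @ self.rotation.T + self.translation

    def validate(self) -> None:
        R = self.rotation
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-8:
            raise AlignmentError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise AlignmentError("reflection is not a valid similarity transform here")
        if self.scale <= 0:
            raise AlignmentError("scale must be positive")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3))


@dataclass
class AverageModel:
    mean_vertices: np.ndarray  # (V, 3) mm
    per_vertex_variance: np.ndarray  # (V,) mm^2
    mean_color: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) reference topology
    n_subjects: int
    filler_fraction: np.ndarray  # (V,) in [0, 1]


def procrustes_pair(
    moving: np.ndarray,
    fixed: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> SimilarityTransform:
    """Closed-form weighted similarity Procrustes: min sum w ||sRx + t - y||^2.

    Weighted centroids, SVD of the weighted cross-covariance with the
    determinant correction (reflections never returned), scale from the
    trace ratio.
    """
    x = np.asarray(moving, dtype=np.float64)
    y = np.asarray(fixed, dtype=np.float64)
    if x.shape != y.shape:
        raise AlignmentError("vertex matrices must have identical shape")
    if weights is None:
        weights = np.ones(len(x))
    w = np.asarray(weights, dtype=np.float64)
    wsum = w.sum()
    if wsum <= 0:
        raise AlignmentError("sum of weights must be positive")
    mx = (w[:, None] * x).sum(axis=0) / wsum
    my = (w[:, None] * y).sum(axis=0) / wsum
    xc = x - mx
    yc = y - my
    C = (w[:, None] * yc).T @ xc  # 3x3 weighted cross-covariance
    U, S, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    denom = float((w * np.einsum("ij,ij->i", xc, xc)).sum())
    if denom <= 0 or S[1] < 1e-12 * max(S[0], 1e-300):
        raise AlignmentError("degenerate (collinear or coincident) configuration")
    s = float((S * np.array([1.0, 1.0, d])).sum() / denom)
    if s <= 0:
        raise AlignmentError("non-positive optimal scale (degenerate input)")
    t = my - s * mx @ R.T
    out = SimilarityTransform(scale=s, rotation=R, translation=t)
    out.validate()
    return out


def centroid_size(x: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    if weights is None:
        weights = np.ones(len(x))
    w = weights / weights.sum()
    c = (w[:, None] * x).sum(axis=0)
    return float(np.sqrt((w * np.sum((x - c) ** 2, axis=1)).sum()))


def generalized_procrustes(
    cohort: CorrespondedCohort,
    tol: float = 1e-8,
    max_iters: int = 50,
):
    """Iterative alignment of all subjects to the evolving mean.

    Weights are 1 - filler per subject.  After each mean update the mean
    is rescaled to unit centroid size ("size-standardized"), so cohorts of
    different absolute scale are comparable; on output everything is
    rescaled once to the cohort's mean centroid size so coordinates stay
    in millimetres.  Deterministic in the input order.  Returns
    (aligned cohort, transforms, objective trace).
    """
    if cohort.n_subjects < 2:
        raise AlignmentError("generalized Procrustes needs at least 2 subjects")
    X = cohort.vertices.copy()  # (S, V, 3)
    W = 1.0 - cohort.filler.astype(np.float64)  # (S, V)
    S_n = cohort.n_subjects
    mean = X[0] / max(centroid_size(X[0], W[0]), 1e-300)
    transforms = [SimilarityTransform.identity() for _ in range(S_n)]
    objective = []
    prev_mean = None
    for _ in range(max_iters):
        for s in range(S_n):
            tr = procrustes_pair(cohort.vertices[s], mean, W[s])
            X[s] = tr.apply(cohort.vertices[s])
            transforms[s] = tr
        mean = X.mean(axis=0)
        cs = centroid_size(mean)
        mean = mean / max(cs, 1e-300)
        obj = float(np.mean((W[..., None] * (X - mean * cs)) ** 2))
        objective.append(obj)
        if prev_mean is not None:
            change = np.linalg.norm(mean - prev_mean) / max(np.linalg.norm(prev_mean), 1e-300)
            if change < tol:
                break
        prev_mean = mean.copy()
    # restore a physical (mm) scale: the cohort's mean centroid size
    target = float(
        np.mean([centroid_size(cohort.vertices[s], W[s]) for s in range(S_n)])
    )
    X = X * target
    for s in range(S_n):
        tr = transforms[s]
        transforms[s] = SimilarityTransform(
            scale=tr.scale * target, rotation=tr.rotation,
            translation=tr.translation * target,
        )
    aligned = CorrespondedCohort(
        vertices=X, color=cohort.color.copy(), filler=cohort.filler.copy(),
        faces=cohort.faces.copy(),
    )
    return aligned, transforms, objective


def average_model(aligned: CorrespondedCohort) -> AverageModel:
    """Arithmetic mean shape with per-vertex scalar variance and mean colour."""
    X = aligned.vertices
    mean = X.mean(axis=0)
    var = np.mean(np.sum((X - mean) ** 2, axis=2), axis=0)
    w = 1.0 - aligned.filler.astype(np.float64)  # (S, V)
    wsum = w.sum(axis=0)
    safe = np.maximum(wsum, 1e-300)
    mean_color = np.einsum("sv,svc->vc", w, aligned.color) / safe[:, None]
    mean_color[wsum == 0] = aligned.color.mean(axis=0)[wsum == 0]
    return AverageModel(
        mean_vertices=mean,
        per_vertex_variance=var,
        mean_color=np.clip(mean_color, 0.0, 1.0),
        faces=aligned.faces.copy(),
        n_subjects=aligned.n_subjects,
        filler_fraction=aligned.filler.mean(axis=0),
    )
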