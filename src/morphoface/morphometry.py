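"""Deviation maps and per-vertex statistics against an average model.

Three complementary read-outs of local facial shape difference:

* **Signed distance maps** — per-vertex displacement of a corresponded
  subject from the average, projected on the average's outward normal
  (positive = outward), rendered with the diverging blue-green-red scheme
  (blue = inward, green = no deviation, red = outward).
* **Tensor-based morphometry (TBM)** — the per-face log area ratio
  log(area_subject / area_average), the surface analogue of the log
  Jacobian determinant; exactly invariant to rigid motion of either mesh
  and shifted by 2 log s under uniform scaling by s.
* **Permutation p-maps** — per-vertex two-group tests of the mean signed
  distance difference under random relabeling of subjects, reported as
  raw p-values (optional Benjamini-Hochberg adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .averaging import AverageModel, procrustes_pair
from .mesh import ColoredMesh, face_areas_normals, vertex_normals_areas
from .registration import CorrespondedCohort


@dataclass
class DistanceMap:
    values: np.ndarray  # (V,) signed mm, positive = outward
    range: tuple  # (lo, hi) display bounds in mm
    colors: np.ndarray  # (V, 3) RGB in [0, 1]


@dataclass
class TBMMap:
    face_values: np.ndarray  # (F,) log area ratio; NaN where undefined
    vertex_values: np.ndarray  # (V,) area-weighted aggregation


@dataclass
class PMap:
    p_values: np.ndarray  # (V,) in (0, 1]
    observed: np.ndarray  # (V,) observed |mean difference| statistic, mm
    n_permutations: int
    seed: int
    statistic: str = "abs mean signed-distance difference"

    def benjamini_hochberg(self) -> np.ndarray:
        """BH-adjusted q-values for the per-vertex p-values."""
        p = self.p_values
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(q, 1.0)
        return out


def _average_normals(average: AverageModel) -> np.ndarray:
    mesh = ColoredMesh.from_arrays(average.mean_vertices, average.faces)
    normals, _ = vertex_normals_areas(mesh)
    return normals


def signed_distance_map(
    subject: np.ndarray,
    average: AverageModel,
    lo: float = -5.0,
    hi: float = 5.0,
    align: bool = False,
) -> DistanceMap:
    """Signed per-vertex distance of a corresponded subject to the average.

    value_v = (subject_v - mean_v) . n_v with n_v the average's outward
    unit vertex normal.  The subject is expected to be Procrustes-aligned
    already; pass ``align=True`` to apply the filler-weighted similarity
    alignment here.
    """
    subject = np.asarray(subject, dtype=np.float64)
    if subject.shape != average.mean_vertices.shape:
        raise ValueError("subject topology does not match the average")
    if align:
        w = 1.0 - average.filler_fraction
        tr = procrustes_pair(subject, average.mean_vertices, w)
        subject = tr.apply(subject)
    n = _average_normals(average)
    values = np.einsum("ij,ij->i", subject - average.mean_vertices, n)
    return DistanceMap(values=values, range=(lo, hi), colors=colorize_values(values, lo, hi))


def colorize_values(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Diverging blue-green-red colour map with exact anchors.

    value <= lo -> (0,0,1); 0 -> (0,1,0); value >= hi -> (1,0,0); linear
    in between, clamped outside.
    """
    if not (lo < 0 < hi):
        raise ValueError("need lo < 0 < hi")
    v = np.asarray(values, dtype=np.float64)
    out = np.zeros(v.shape + (3,))
    neg = v < 0
    t_neg = np.clip(v / lo, 0.0, 1.0)  # 0 at value 0, 1 at value lo
    t_pos = np.clip(v / hi, 0.0, 1.0)
    out[..., 0] = np.where(neg, 0.0, t_pos)
    out[..., 1] = np.where(neg, 1.0 - t_neg, 1.0 - t_pos)
    out[..., 2] = np.where(neg, t_neg, 0.0)
    return out


def colorize(dmap: DistanceMap, lo: float, hi: float) -> np.ndarray:
    return colorize_values(dmap.values, lo, hi)


def unsigned_distance_map(subject: np.ndarray, average: AverageModel) -> np.ndarray:
    """Euclidean per-vertex distance (the unsigned variant)."""
    return np.linalg.norm(subject - average.mean_vertices, axis=1)


def tbm_map(subject: np.ndarray, average: AverageModel) -> TBMMap:
    """Per-face log area ratio of subject over average (TBM feature)."""
    subject = np.asarray(subject, dtype=np.float64)
    if subject.shape != average.mean_vertices.shape:
        raise ValueError("subject topology does not match the average")
    fa_s, _ = face_areas_normals(subject, average.faces)
    fa_a, _ = face_areas_normals(average.mean_vertices, average.faces)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(fa_a > 0, np.log(np.maximum(fa_s, 1e-300) / np.where(fa_a > 0, fa_a, 1.0)), np.nan)
    # aggregate to vertices, area-weighted, skipping undefined faces
    V = len(subject)
    num = np.zeros(V)
    den = np.zeros(V)
    ok = np.isfinite(vals)
    for k in range(3):
        np.add.at(num, average.faces[ok, k], vals[ok] * fa_a[ok])
        np.add.at(den, average.faces[ok, k], fa_a[ok])
    vertex_vals = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return TBMMap(face_values=vals, vertex_values=vertex_vals)


def permutation_pmap(
    group_a: CorrespondedCohort,
    group_b: CorrespondedCohort,
    average: AverageModel,
    n_perm: int = 999,
    seed: int = 0,
) -> PMap:
    """Per-vertex permutation test of group mean signed-distance difference.

    Statistic: |mean signed distance in A - mean in B| (distances to the
    pooled average); the null is generated by random relabeling of the
    subjects into groups of the original sizes.
    p = (1 + #{null >= observed}) / (n_perm + 1); the smallest attainable
    p is 1/(n_perm + 1).  No multiplicity correction by default.
    """
    if group_a.n_subjects < 2 or group_b.n_subjects < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = _average_normals(average)
    da = np.einsum("svj,vj->sv", group_a.vertices - average.mean_vertices, n)
    db = np.einsum("svj,vj->sv", group_b.vertices - average.mean_vertices, n)
    D = np.vstack([da, db])  # (S_a + S_b, V)
    na = group_a.n_subjects
    observed = np.abs(D[:na].mean(axis=0) - D[na:].mean(axis=0))
    rng = np.random.default_rng(seed)
    count = np.zeros(D.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(D.shape[0])
        null = np.abs(D[perm[:na]].mean(axis=0) - D[perm[na:]].mean(axis=0))
        count += null >= observed
    p = (1.0 + count) / (n_perm + 1.0)
    return PMap(p_values=p, observed=observed, n_permutations=n_perm, seed=seed)


def compare_averages(
    avg_a: AverageModel,
    avg_b: AverageModel,
    lo: float = -3.0,
    hi: float = 3.0,
) -> DistanceMap:
    """Signed distance of average B against average A after alignment.

    B's mean is Procrustes-aligned to A's (weights = 1 - filler fraction),
    then mapped exactly like an individual subject.
    """
    if avg_a.mean_vertices.shape != avg_b.mean_vertices.shape or \
            avg_a.faces.shape != avg_b.faces.shape:
        raise ValueError("averages are not on the same reference topology")
    w = np.minimum(1.0 - avg_a.filler_fraction, 1.0 - avg_b.filler_fraction)
    if w.sum() <= 0:
        w = np.ones(len(w))
    tr = procrustes_pair(avg_b.mean_vertices, avg_a.mean_vertices, w)
    aligned_b = tr.apply(avg_b.mean_vertices)
    return signed_distance_map(aligned_b, avg_a, lo=lo, hi=hi)
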