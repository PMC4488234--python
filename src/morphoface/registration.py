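"""Dense spherical correspondence between subjects.

A moving subject's sphere is deformed onto a fixed subject's sphere in two
steps.  A *curve-based initialization* turns matched anatomical curves
(sampled uniformly by surface arclength) into point pairs, blends the pair
rotations into a smooth dense field, and produces an initial warp.  A
*fluid refinement* then iterates: the per-vertex negative gradient of the
mismatch cost (multi-channel texture mutual information plus curvature
mean-squared difference) is smoothed with a spherical Gaussian kernel into
a velocity field, and the warp is composed with a small tangential step of
that velocity.  Steps are accepted only when they keep the warped
triangulation flip-free and decrease the cost, so the cost trace is
strictly decreasing and the warp stays a bijection surrogate.

Filler vertices (synthesized hole patches) carry no anatomy: they are
excluded from the mismatch cost on both sides, which lets extraneous
tissue in one scan match filler regions in another without penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .mesh import ColoredMesh, CurveSet, curvatures
from .sphere import (
    SphereLocator,
    SphericalMap,
    count_flips,
    _normalize_rows,
)


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class SphericalWarp:
    """Where each moving-sphere vertex lands on the fixed sphere."""

    domain: SphericalMap
    warped_positions: np.ndarray  # (V, 3) unit vectors

    def validate(self) -> None:
        norms = np.linalg.norm(self.warped_positions, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            raise RegistrationError("warped positions must be unit vectors")
        if count_flips(self.warped_positions, self.domain.faces) > 0:
            raise RegistrationError("warp contains flipped triangles")

    @property
    def is_flip_free(self) -> bool:
        return count_flips(self.warped_positions, self.domain.faces) == 0

    @classmethod
    def identity(cls, domain: SphericalMap) -> "SphericalWarp":
        return cls(domain=domain, warped_positions=domain.sphere_positions.copy())


@dataclass
class RegistrationParams:
    w_texture: float = 1.0
    w_geometry: float = 1.0
    mi_bins: int = 32
    kernel_sigma: float = 0.1  # radians
    step: float = 0.5
    max_iters: int = 200
    tol: float = 1e-5
    seed: int = 0
    grad_h: float = 1e-3  # radians, central-difference probe

    def validate(self) -> None:
        if self.w_texture < 0 or self.w_geometry < 0 or self.w_texture + self.w_geometry <= 0:
            raise ValueError("need w_texture + w_geometry > 0, both non-negative")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")


@dataclass
class FeatureChannels:
    """Per-vertex matching channels: R, G, B, mean curvature, Gaussian curvature.

    Texture channels stay in [0, 1]; curvature channels are robust
    z-normalized (zero median, unit median-absolute-deviation) over the
    valid (non-filler) mask so they are comparable across subjects.
    """

    texture: np.ndarray  # (V, 3)
    geometry: np.ndarray  # (V, 2) robust-z curvatures
    valid: np.ndarray  # (V,) bool, True where not filler

    @classmethod
    def from_mesh(cls, mesh: ColoredMesh) -> "FeatureChannels":
        cf = curvatures(mesh)
        geom = np.stack([cf.mean_curvature, cf.gaussian_curvature], axis=1)
        valid = ~mesh.filler
        gz = np.empty_like(geom)
        for k in range(geom.shape[1]):
            col = geom[:, k]
            med = np.median(col[valid])
            mad = np.median(np.abs(col[valid] - med))
            if mad <= 0:
                mad = 1.0
            gz[:, k] = (col - med) / mad
        return cls(texture=mesh.color.copy(), geometry=gz, valid=valid)

    @property
    def all_channels(self) -> np.ndarray:
        return np.hstack([self.texture, self.geometry])


@dataclass
class Subject:
    """Everything registration needs about one scan."""

    mesh: ColoredMesh
    sphmap: SphericalMap
    curves: Optional[CurveSet] = None
    channels: Optional[FeatureChannels] = None

    def __post_init__(self):
        if self.channels is None:
            self.channels = FeatureChannels.from_mesh(self.mesh)


@dataclass
class CorrespondedCohort:
    """Subjects resampled onto one reference topology (correspondence by index)."""

    vertices: np.ndarray  # (S, V, 3) mm
    color: np.ndarray  # (S, V, 3)
    filler: np.ndarray  # (S, V) bool
    faces: np.ndarray  # (F, 3) reference topology

    @property
    def n_subjects(self) -> int:
        return self.vertices.shape[0]


# ---------------------------------------------------------------------------
# curve correspondence and initial warp
# ---------------------------------------------------------------------------


def _resample_curve(mesh: ColoredMesh, sphmap: SphericalMap, idx, n_samples: int):
    """Sample a vertex polyline at equal normalized surface arclength.

    Returns (n_samples, 3) unit sphere positions.  Arclength is measured on
    the 3D polyline; sphere positions are interpolated within segments.
    """
    idx = np.asarray(idx, dtype=np.int64)
    pts = mesh.vertices[idx]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise RegistrationError("zero-length curve")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n_samples)
    j = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seg) - 1)
    t = (targets - cum[j]) / np.maximum(seg[j], 1e-300)
    t = np.clip(t, 0.0, 1.0)
    sp = sphmap.sphere_positions[idx]
    out = (1 - t)[:, None] * sp[j] + t[:, None] * sp[j + 1]
    return _normalize_rows(out)


def curve_correspondence(
    moving: Subject, fixed: Subject, n_samples: int = 15
):
    """Arclength-matched point pairs on the two spheres, per named curve."""
    cm, cf = moving.curves, fixed.curves
    if cm is None or cf is None:
        raise RegistrationError("both subjects need curve sets")
    missing = set(cm.curves) ^ set(cf.curves)
    if missing:
        raise RegistrationError(f"curve name(s) not shared: {sorted(missing)}")
    pairs_m, pairs_f = [], []
    for name in sorted(cm.curves):
        pm = _resample_curve(moving.mesh, moving.sphmap, cm.curves[name], n_samples)
        pf = _resample_curve(fixed.mesh, fixed.sphmap, cf.curves[name], n_samples)
        pairs_m.append(pm)
        pairs_f.append(pf)
    return np.vstack(pairs_m), np.vstack(pairs_f)


def _pair_rotation_vectors(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation vector (axis * angle) taking each src direction to dst."""
    cross = np.cross(src, dst)
    sin = np.linalg.norm(cross, axis=1)
    cos = np.einsum("ij,ij->i", src, dst)
    ang = np.arctan2(sin, cos)
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(sin[:, None] > 1e-15, cross / np.maximum(sin, 1e-300)[:, None], 0.0)
    return axis * ang[:, None]


def _apply_rotation_vectors(points: np.ndarray, rvecs: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of each point by its own rotation vector."""
    theta = np.linalg.norm(rvecs, axis=1)
    small = theta < 1e-14
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(small[:, None], 0.0, rvecs / np.maximum(theta, 1e-300)[:, None])
    cos = np.cos(theta)[:, None]
    sin = np.sin(theta)[:, None]
    kxp = np.cross(k, points)
    kdp = np.einsum("ij,ij->i", k, points)[:, None]
    out = points * cos + kxp * sin + k * kdp * (1 - cos)
    return np.where(small[:, None], points, out)


def initial_warp(
    pairs_moving: np.ndarray,
    pairs_fixed: np.ndarray,
    domain: SphericalMap,
    kernel_sigma: float = 0.2,
) -> SphericalWarp:
    """Dense warp from matched point pairs by rotation-vector blending.

    The displacement at each pair is the great-circle rotation taking the
    moving point to its fixed partner; the dense field is the spherical-
    Gaussian-weighted blend of those rotation vectors, applied to every
    domain vertex and re-projected.  The blended field is flip-guarded by
    global amplitude halving.
    """
    pm = np.asarray(pairs_moving, dtype=np.float64)
    pf = np.asarray(pairs_fixed, dtype=np.float64)
    if len(pm) < 3:
        raise RegistrationError("need at least 3 correspondence pairs")
    # global component first (orthogonal Procrustes on the directions), so a
    # shared head rotation is removed exactly and the blended field only
    # carries the residual local displacements
    u, _, vt = np.linalg.svd(pf.T @ pm)
    Rg = u @ np.diag([1.0, 1.0, np.linalg.det(u @ vt)]) @ vt
    pm_rot = pm @ Rg.T
    rvec = _pair_rotation_vectors(pm_rot, pf)
    x = domain.sphere_positions @ Rg.T
    cosd = np.clip(x @ pm_rot.T, -1.0, 1.0)
    d = np.arccos(cosd)  # (V, K)
    w = np.exp(-0.5 * (d / kernel_sigma) ** 2) + 1e-30
    w = w / w.sum(axis=1, keepdims=True)
    field = w @ rvec  # (V, 3) blended residual rotation vectors
    amp = 1.0
    for _ in range(21):
        warped = _normalize_rows(_apply_rotation_vectors(x, amp * field))
        if count_flips(warped, domain.faces) == 0:
            return SphericalWarp(domain=domain, warped_positions=warped)
        amp *= 0.5
    raise RegistrationError("initial warp has flips even after 20 amplitude halvings")


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


def mutual_information_full(a, b, bins: int = 32):
    """Plug-in mutual information in bits; returns (mi, degenerate_flag).

    Joint histogram with ``bins`` x ``bins`` equal-width bins over each
    variable's observed range, MI = sum p(i,j) log2(p(i,j)/(p(i) p(j))).
    A constant channel yields MI = 0 with the degenerate flag set.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if len(a) != len(b):
        raise ValueError("samples must have equal length")
    if len(a) < bins:
        raise ValueError("need at least `bins` samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0, True
    h, _, _ = np.histogram2d(a, b, bins=bins)
    return _mi_from_counts(h), False


def mutual_information(a, b, bins: int = 32) -> float:
    mi, degenerate = mutual_information_full(a, b, bins)
    if degenerate:
        warnings.warn("degenerate (constant) channel: MI = 0", RuntimeWarning, stacklevel=2)
    return mi


def _mi_from_counts(h: np.ndarray) -> float:
    import math

    n = h.sum()
    pj = h.sum(axis=1)
    pk = h.sum(axis=0)
    nz = h > 0
    hv = h[nz]
    outer = np.outer(pj, pk)[nz]
    # fsum is exactly rounded, hence order-independent: MI(a,b) == MI(b,a)
    return math.fsum(hv / n * np.log2(hv * n / outer))


# ---------------------------------------------------------------------------
# registration cost
# ---------------------------------------------------------------------------


class _FixedSampler:
    """Caches the fixed subject's locator and channel matrix."""

    def __init__(self, fixed: Subject):
        self.locator = SphereLocator(
            fixed.sphmap.sphere_positions, fixed.sphmap.faces
        )
        ch = fixed.channels
        self.channels = ch.all_channels  # (V, 5)
        self.invalid = (~ch.valid).astype(np.float64)  # filler indicator

    def sample(self, points: np.ndarray):
        """Returns (channel samples (n,5), filler_contact (n,) bool)."""
        fidx, w = self.locator.locate(points)
        vals = np.einsum("nk,nkj->nj", w, self.channels[self.locator.faces[fidx]])
        fill = np.einsum("nk,nk->n", w, self.invalid[self.locator.faces[fidx]])
        return vals, fill > 1e-9


def registration_cost(
    warp: SphericalWarp,
    moving: Subject,
    fixed: Subject,
    params: RegistrationParams,
    sampler: Optional[_FixedSampler] = None,
    return_breakdown: bool = False,
):
    """Mismatch cost of a warp: -w_t * sum_RGB MI + w_g * curvature MSD.

    Fixed-subject channels are sampled at the warped positions of valid
    moving vertices; any pair touching filler on either side is excluded.
    """
    params.validate()
    if not warp.is_flip_free:
        raise RegistrationError("registration_cost requires a flip-free warp")
    if sampler is None:
        sampler = _FixedSampler(fixed)
    mch = moving.channels
    vals, fill = sampler.sample(warp.warped_positions)
    valid = mch.valid & ~fill
    n_valid = int(valid.sum())
    if n_valid < params.mi_bins:
        raise RegistrationError(
            f"only {n_valid} valid samples for {params.mi_bins} histogram bins"
        )
    tex_term = 0.0
    mis = []
    if params.w_texture > 0:
        for c in range(3):
            mi, _ = mutual_information_full(
                mch.texture[valid, c], vals[valid, c], params.mi_bins
            )
            mis.append(mi)
        tex_term = -params.w_texture * float(np.sum(mis))
    geo_term = 0.0
    if params.w_geometry > 0:
        diff = mch.geometry[valid] - vals[valid][:, 3:5]
        geo_term = params.w_geometry * float(np.mean(diff**2))
    cost = tex_term + geo_term
    if return_breakdown:
        return cost, {"texture": tex_term, "geometry": geo_term, "mi_per_channel": mis,
                      "n_valid": n_valid}
    return cost


# ---------------------------------------------------------------------------
# fluid refinement
# ---------------------------------------------------------------------------


def _tangent_basis(p: np.ndarray):
    """Orthonormal tangent frames (e1, e2) at unit points p."""
    ref = np.where(np.abs(p[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = _normalize_rows(np.cross(ref, p))
    e2 = np.cross(p, e1)
    return e1, e2


def _delta_mi_move(h, j, k0, k1):
    """Exact MI change (bits) when one sample moves f-bin k0 -> k1 in row j.

    Vectorized over probes: j, k0, k1 are (n,) int arrays into a shared
    joint-count matrix h.  The a-marginal is unchanged, so
    dMI = dH(F) - dH(A, F).
    """
    n = h.sum()

    def hterm(x):
        x = np.maximum(x, 0.0)
        out = np.zeros_like(x, dtype=np.float64)
        nz = x > 0
        out[nz] = -(x[nz] / n) * np.log2(x[nz] / n)
        return out

    ck = h.sum(axis=0)
    same = k0 == k1
    d_hf = (
        hterm(ck[k0] - 1.0) + hterm(ck[k1] + 1.0) - hterm(ck[k0]) - hterm(ck[k1])
    )
    njk0 = h[j, k0]
    njk1 = h[j, k1]
    d_hjoint = (
        hterm(njk0 - 1.0) + hterm(njk1 + 1.0) - hterm(njk0) - hterm(njk1)
    )
    out = d_hf - d_hjoint
    out[same] = 0.0
    return out


def fluid_register(
    moving: Subject,
    fixed: Subject,
    init: Optional[SphericalWarp] = None,
    params: Optional[RegistrationParams] = None,
):
    """Greedy fluid refinement of a spherical warp (see module docstring).

    Returns (warp, cost_trace).  The trace holds the cost after every
    accepted step (strictly decreasing); the first entry is the cost of
    the initial warp.
    """
    if params is None:
        params = RegistrationParams()
    params.validate()
    if init is None:
        init = SphericalWarp.identity(moving.sphmap)
    if not init.is_flip_free:
        raise RegistrationError("initial warp has flipped triangles")
    sampler = _FixedSampler(fixed)
    warp = SphericalWarp(domain=init.domain, warped_positions=init.warped_positions.copy())
    faces = warp.domain.faces
    mch = moving.channels
    h_probe = params.grad_h
    cost = registration_cost(warp, moving, fixed, params, sampler=sampler)
    trace = [cost]
    step = params.step
    for _ in range(params.max_iters):
        p = warp.warped_positions
        vals, fill = sampler.sample(p)
        valid = mch.valid & ~fill
        n_valid = int(valid.sum())
        # current histograms / bin edges per texture channel
        tex_hists = []
        if params.w_texture > 0:
            for c in range(3):
                a = mch.texture[valid, c]
                b = vals[valid, c]
                a_edges = np.linspace(a.min(), a.max(), params.mi_bins + 1)
                b_edges = np.linspace(b.min(), b.max(), params.mi_bins + 1)
                hst, _, _ = np.histogram2d(a, b, bins=[a_edges, b_edges])
                a_bin_full = np.clip(
                    np.searchsorted(a_edges, mch.texture[:, c], side="right") - 1,
                    0, params.mi_bins - 1,
                )
                b_bin_cur = np.clip(
                    np.searchsorted(b_edges, vals[:, c], side="right") - 1,
                    0, params.mi_bins - 1,
                )
                tex_hists.append((hst, a_edges, b_edges, a_bin_full, b_bin_cur))
        e1, e2 = _tangent_basis(p)
        force = np.zeros_like(p)
        geo_scale = params.w_geometry / max(n_valid, 1) / 2.0  # 2 curvature channels
        for basis, out_axis in ((e1, 0), (e2, 1)):
            deltas = []
            for sgn in (+1.0, -1.0):
                q = _normalize_rows(p + sgn * h_probe * basis)
                vq, fq = sampler.sample(q)
                dcost = np.zeros(len(p))
                if params.w_geometry > 0:
                    d_new = np.sum((mch.geometry - vq[:, 3:5]) ** 2, axis=1)
                    d_old = np.sum((mch.geometry - vals[:, 3:5]) ** 2, axis=1)
                    dcost += geo_scale * (d_new - d_old)
                if params.w_texture > 0:
                    for c, (hst, a_edges, b_edges, a_bin, b_bin) in enumerate(tex_hists):
                        b_new = np.clip(
                            np.searchsorted(b_edges, vq[:, c], side="right") - 1,
                            0, params.mi_bins - 1,
                        )
                        dmi = _delta_mi_move(hst, a_bin, b_bin, b_new)
                        dcost += -params.w_texture * dmi
                dcost[~valid] = 0.0
                deltas.append(dcost)
            grad_d = (deltas[0] - deltas[1]) / (2.0 * h_probe)
            force -= grad_d[:, None] * basis
        # spherical Gaussian smoothing of the force into a velocity field
        cosm = np.clip(p @ p.T, -1.0, 1.0)
        dm = np.arccos(cosm)
        K = np.exp(-0.5 * (dm / params.kernel_sigma) ** 2)
        K = K / K.sum(axis=1, keepdims=True)
        vel = K @ force
        vel = vel - np.einsum("ij,ij->i", vel, p)[:, None] * p
        vmax = np.linalg.norm(vel, axis=1).max()
        if vmax < 1e-14:
            break
        # normalized step: `step` is the maximum vertex motion in radians
        s = step / vmax
        accepted = False
        for _ in range(11):
            q = _normalize_rows(p + s * vel)
            if count_flips(q, faces) == 0:
                trial = SphericalWarp(domain=warp.domain, warped_positions=q)
                try:
                    new_cost = registration_cost(
                        trial, moving, fixed, params, sampler=sampler
                    )
                except RegistrationError:
                    new_cost = np.inf
                if new_cost < cost:
                    warp = trial
                    rel = (cost - new_cost) / max(abs(cost), 1e-300)
                    cost = new_cost
                    trace.append(cost)
                    accepted = True
                    break
            s *= 0.5
        if not accepted:
            break
        if rel < params.tol:
            break
    return warp, trace


# ---------------------------------------------------------------------------
# resampling onto a reference topology
# ---------------------------------------------------------------------------


def resample_to_reference(
    subjects: Sequence[Subject],
    reference: SphericalMap,
    warps: Sequence[SphericalWarp],
) -> CorrespondedCohort:
    """Pull every subject onto the reference topology via its warp.

    For each reference vertex direction the subject's warped triangulation
    is searched (inverting the warp), and position, colour and filler are
    barycentrically interpolated.  A resampled vertex is filler if any
    contributing subject vertex is filler.
    """
    if len(subjects) != len(warps):
        raise ValueError("one warp per subject required")
    q = reference.sphere_positions
    n_ref = len(q)
    S = len(subjects)
    verts = np.empty((S, n_ref, 3))
    cols = np.empty((S, n_ref, 3))
    fill = np.empty((S, n_ref), dtype=bool)
    for s, (sub, warp) in enumerate(zip(subjects, warps)):
        if not warp.is_flip_free:
            raise RegistrationError(f"subject {s}: warp has flips, cannot invert")
        loc = SphereLocator(warp.warped_positions, warp.domain.faces)
        fidx, w = loc.locate(q)
        tri = warp.domain.faces[fidx]
        verts[s] = np.einsum("nk,nkj->nj", w, sub.mesh.vertices[tri])
        cols[s] = np.einsum("nk,nkj->nj", w, sub.mesh.color[tri])
        fill[s] = (sub.mesh.filler[tri] & (w > 1e-9)).any(axis=1)
    return CorrespondedCohort(
        vertices=verts, color=cols, filler=fill, faces=reference.faces.copy()
    )
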