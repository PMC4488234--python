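"""Spherical parameterization of closed genus-zero meshes.

Every corrected surface is mapped to the unit sphere, the canonical space
where cross-subject correspondence is computed.  The map is built in three
stages:

1. *Conformal initialization* — central projection from the area centroid
   (flip-free for the star-shaped surfaces produced by facial scans),
   followed by projected cotangent-Laplacian relaxation on the sphere: the
   tangential Laplacian (with weights from the *source* geometry) is
   stepped until vertex displacements fall below a tolerance, which drives
   the map toward the minimizer of harmonic energy, i.e. a conformal map
   up to Möbius factors.
2. *Möbius centering* — the spherical inversion that moves the
   area-weighted centroid of the image to the origin, fixing the Möbius
   ambiguity.
3. *Area relaxation* — explicit tangential gradient descent on the
   area-distortion objective ``sum_f (area_ratio_f - 1)^2`` (spherical
   face-area fraction over surface face-area fraction), accepting only
   flip-free, objective-decreasing steps.

All steps are flip-guarded: a step that reverses the spherical orientation
of any face is halved and retried.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .mesh import (
    ColoredMesh,
    cotangent_laplacian,
    diagnose,
    face_areas_normals,
    face_edges,
)
import scipy.sparse as sparse


def _sp_adjacency(edges, n):
    return sparse.coo_matrix(
        (np.ones(2 * len(edges)),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    ).tocsr()


class SphericalMapError(RuntimeError):
    pass


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def spherical_triangle_areas(p: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Spherical face areas by l'Huilier's formula (unit sphere)."""
    a_ = p[faces[:, 0]]
    b_ = p[faces[:, 1]]
    c_ = p[faces[:, 2]]

    def arc(u, v):
        # numerically stable arc length
        return 2.0 * np.arcsin(np.clip(0.5 * np.linalg.norm(u - v, axis=1), -1, 1))

    a = arc(b_, c_)
    b = arc(a_, c_)
    c = arc(a_, b_)
    s = 0.5 * (a + b + c)
    t = (
        np.tan(s / 2) * np.tan((s - a) / 2) * np.tan((s - b) / 2) * np.tan((s - c) / 2)
    )
    return 4.0 * np.arctan(np.sqrt(np.maximum(t, 0.0)))


def face_orientations(p: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Sign of det[p_i, p_j, p_k] per face (spherical orientation)."""
    return np.sign(
        np.einsum(
            "ij,ij->i",
            p[faces[:, 0]],
            np.cross(p[faces[:, 1]], p[faces[:, 2]]),
        )
    )


def count_flips(p: np.ndarray, faces: np.ndarray) -> int:
    s = face_orientations(p, faces)
    pos = int((s > 0).sum())
    neg = int((s < 0).sum())
    return min(pos, neg) + int((s == 0).sum())


@dataclass
class SphericalMap:
    """Unit-sphere vertex positions sharing the source triangulation."""

    sphere_positions: np.ndarray  # (V, 3) unit vectors
    faces: np.ndarray  # (F, 3), shared with source
    source: ColoredMesh

    def validate(self) -> None:
        norms = np.linalg.norm(self.sphere_positions, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            raise SphericalMapError("sphere positions must be unit vectors")
        if count_flips(self.sphere_positions, self.faces) > 0:
            raise SphericalMapError("spherical map contains flipped triangles")


@dataclass
class MapQuality:
    n_flipped: int
    area_ratio: np.ndarray  # per-face spherical fraction / surface fraction
    conformal_distortion: np.ndarray  # per-face quasi-conformal distortion >= 1


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------


def _area_centroid(mesh: ColoredMesh) -> np.ndarray:
    fa, _ = face_areas_normals(mesh.vertices, mesh.faces)
    fc = mesh.vertices[mesh.faces].mean(axis=1)
    return (fa[:, None] * fc).sum(axis=0) / fa.sum()


def _area_weighted_sphere_centroid(
    p: np.ndarray, faces: np.ndarray, source_areas: Optional[np.ndarray] = None
) -> np.ndarray:
    """Where the *surface* mass sits on the sphere.

    Weights are source-surface face areas (spherical-area weights would
    integrate x over the whole sphere and vanish for any bijection, which
    measures nothing).  Zero iff the map spreads the surface evenly around
    the origin — the quantity the Möbius normalization drives to zero.
    """
    if source_areas is None:
        source_areas = np.ones(len(faces))
    fc = _normalize_rows(p[faces].mean(axis=1))
    return (source_areas[:, None] * fc).sum(axis=0) / source_areas.sum()


def _mobius_center(
    p: np.ndarray,
    faces: np.ndarray,
    source_areas: Optional[np.ndarray] = None,
    tol: float = 1e-7,
    max_iter: int = 500,
):
    """Spherical inversions moving the source-mass centroid to the origin."""
    p = p.copy()
    step = 0.5
    for _ in range(max_iter):
        c = _area_weighted_sphere_centroid(p, faces, source_areas)
        if np.linalg.norm(c) < tol:
            break
        # inversion x -> ((1-|a|^2)(x+a))/|x+a|^2 + a pulls mass toward -a,
        # so step against the centroid
        a = step * c
        denom = np.sum((p + a) ** 2, axis=1, keepdims=True)
        q = (1.0 - np.sum(a**2)) * (p + a) / denom + a
        q = _normalize_rows(q)
        cq = _area_weighted_sphere_centroid(q, faces, source_areas)
        if np.linalg.norm(cq) >= np.linalg.norm(c):
            a = -step * c
            denom = np.sum((p + a) ** 2, axis=1, keepdims=True)
            q = _normalize_rows((1.0 - np.sum(a**2)) * (p + a) / denom + a)
            cq = _area_weighted_sphere_centroid(q, faces, source_areas)
            if np.linalg.norm(cq) >= np.linalg.norm(c):
                step *= 0.5
                if step < 1e-4:
                    break
                continue
        p = q
    return p


def area_distortion_objective(p: np.ndarray, mesh: ColoredMesh) -> float:
    sa = spherical_triangle_areas(p, mesh.faces)
    fa, _ = face_areas_normals(mesh.vertices, mesh.faces)
    ratio = (sa / sa.sum()) / np.maximum(fa / fa.sum(), 1e-300)
    return float(np.sum((ratio - 1.0) ** 2))


def spherical_parameterize(
    mesh: ColoredMesh,
    area_relax_iters: int = 100,
    conformal_tol: float = 1e-7,
    conformal_max_iter: int = 2000,
) -> SphericalMap:
    """Map a closed genus-zero mesh to the unit sphere (see module docs)."""
    d = diagnose(mesh)
    if not (d.is_closed and d.is_manifold and d.genus == 0):
        raise SphericalMapError(
            f"spherical parameterization requires a closed genus-0 manifold "
            f"(closed={d.is_closed}, manifold={d.is_manifold}, genus={d.genus})"
        )
    faces = mesh.faces
    source_fa, _ = face_areas_normals(mesh.vertices, faces)
    # stage 1a: central-projection seeding.  Exactly flip-free for
    # star-shaped scans; surfaces with deep flat hole patches (e.g. a sewn
    # neck membrane) are progressively inflated (uniform Laplacian
    # smoothing of a geometry copy) until their projection unfolds.
    edges, _, _ = face_edges(faces)
    n_v = len(mesh.vertices)
    A = _sp_adjacency(edges, n_v)
    adeg = np.asarray(A.sum(axis=1)).ravel()
    adeg[adeg == 0] = 1.0
    geom = mesh.vertices.copy()
    p = None
    for _ in range(12):
        fa_g, _ = face_areas_normals(geom, faces)
        fc = geom[faces].mean(axis=1)
        center = (fa_g[:, None] * fc).sum(axis=0) / max(fa_g.sum(), 1e-300)
        cand = _normalize_rows(geom - center)
        if p is None or count_flips(cand, faces) < count_flips(p, faces):
            p = cand
        if count_flips(p, faces) == 0:
            break
        for _ in range(25):
            geom = 0.5 * geom + 0.5 * (A @ geom) / adeg[:, None]
    # stage 1b: projected cotangent-Laplacian relaxation (conformal
    # smoothing).  Off-diagonal weights are clipped positive so the skinny
    # triangles a sewn patch contains cannot destabilize the iteration; the
    # smoothing itself is contracting and untangles folds left by seeding.
    W = cotangent_laplacian(mesh.vertices, faces).tocoo()
    off = W.row != W.col
    data = np.where(off, np.maximum(W.data, 1e-8), 0.0)
    import scipy.sparse as _sp

    W2 = _sp.coo_matrix((data, (W.row, W.col)), shape=W.shape).tocsr()
    W = W2 - _sp.diags(np.asarray(W2.sum(axis=1)).ravel())
    deg = np.abs(W.diagonal())
    deg[deg == 0] = 1.0
    step = 0.5

    def smooth_guarded(p, max_iter):
        # flip-guarded: a step may never increase the flip count
        for _ in range(max_iter):
            lap = (W @ p) / deg[:, None]  # normalized Laplacian displacement
            tang = lap - np.einsum("ij,ij->i", lap, p)[:, None] * p
            base_flips = count_flips(p, faces)
            trial = step
            q = p
            for _ in range(20):
                cand = _normalize_rows(p + trial * tang)
                # keep the iteration centered to prevent Möbius collapse
                cand = _normalize_rows(
                    cand - _area_weighted_sphere_centroid(cand, faces, source_fa)
                )
                if count_flips(cand, faces) <= base_flips:
                    q = cand
                    break
                trial *= 0.5
            disp = np.linalg.norm(q - p, axis=1).max()
            p = q
            if disp < conformal_tol:
                break
        return p

    def untangle_local(p, max_passes=100):
        # Gauss-Seidel averaging of the vertices touching flipped faces:
        # folds are local artefacts of degenerate patch triangles
        nbrs = [set() for _ in range(len(p))]
        for tri in faces:
            a, b, c = (int(x) for x in tri)
            nbrs[a].update((b, c))
            nbrs[b].update((a, c))
            nbrs[c].update((a, b))
        gs = 1.0 if (face_orientations(p, faces) >= 0).mean() >= 0.5 else -1.0
        prev_bad = None
        depth = 1
        for _ in range(max_passes):
            bad = faces[face_orientations(p, faces) * gs <= 0]
            if len(bad) == 0:
                break
            verts = set(int(v) for v in np.unique(bad))
            if prev_bad is not None and len(bad) >= prev_bad:
                depth = min(depth + 1, 4)  # stagnating: widen the stencil
            prev_bad = len(bad)
            region = set(verts)
            for _ in range(depth - 1):
                region |= {n for v in region for n in nbrs[v]}
            for v in region:
                ring = list(nbrs[v])
                p[v] = p[ring].mean(axis=0)
                p[v] /= np.linalg.norm(p[v])
        return p

    p = smooth_guarded(p, conformal_max_iter)
    for _ in range(5):
        if count_flips(p, faces) == 0:
            break
        p = untangle_local(p.copy())
        p = smooth_guarded(p, 200)
    # stage 2: Möbius normalization
    p = _mobius_center(p, faces, source_fa)
    if count_flips(p, faces) > 0:
        raise SphericalMapError(
            f"conformal stage left {count_flips(p, faces)} flipped triangles"
        )
    # stage 3: area-equalizing tangential relaxation
    p = _area_relax(p, mesh, area_relax_iters)
    # relaxation drifts the centroid slightly; re-center (Möbius maps
    # preserve orientation, so flip-freedom survives)
    p = _mobius_center(p, faces, source_fa)
    sphmap = SphericalMap(sphere_positions=p, faces=faces, source=mesh)
    sphmap.validate()
    return sphmap


def _area_relax(p: np.ndarray, mesh: ColoredMesh, iters: int, step0: float = 0.05):
    """Gradient descent on sum((area_ratio-1)^2), flip-guarded, monotone."""
    faces = mesh.faces
    fa, _ = face_areas_normals(mesh.vertices, mesh.faces)
    target_frac = fa / fa.sum()
    obj = area_distortion_objective(p, mesh)
    for _ in range(max(0, iters)):
        # descent direction from planar-area surrogate gradients
        sa = spherical_triangle_areas(p, faces)
        tot = sa.sum()
        ratio = (sa / tot) / np.maximum(target_frac, 1e-300)
        resid = ratio - 1.0  # dE/d(spherical fraction) ~ 2*resid/target
        coef = 2.0 * resid / np.maximum(target_frac, 1e-300) / tot
        grad = np.zeros_like(p)
        a, b, c = p[faces[:, 0]], p[faces[:, 1]], p[faces[:, 2]]
        cr = np.cross(b - a, c - a)
        n = cr / np.maximum(np.linalg.norm(cr, axis=1, keepdims=True), 1e-300)
        for k, (u, v) in enumerate(((1, 2), (2, 0), (0, 1))):
            # d(planar area)/d p_k = 0.5 * n x (p_v - p_u)... sign per winding
            gk = 0.5 * np.cross(n, p[faces[:, v]] - p[faces[:, u]])
            np.add.at(grad, faces[:, k], coef[:, None] * gk)
        tang = -(grad - np.einsum("ij,ij->i", grad, p)[:, None] * p)
        gn = np.linalg.norm(tang, axis=1).max()
        if gn < 1e-14:
            break
        t = step0 / gn
        accepted = False
        for _ in range(20):
            q = _normalize_rows(p + t * tang)
            if count_flips(q, faces) == 0:
                new_obj = area_distortion_objective(q, mesh)
                if new_obj < obj:
                    p, obj_prev, obj = q, obj, new_obj
                    accepted = True
                    break
            t *= 0.5
        if not accepted:
            break
        if (obj_prev - obj) / max(obj_prev, 1e-300) < 1e-6:
            break
    return p


# ---------------------------------------------------------------------------
# quality audit
# ---------------------------------------------------------------------------


def map_quality(sphmap: SphericalMap) -> MapQuality:
    p, faces, mesh = sphmap.sphere_positions, sphmap.faces, sphmap.source
    n_flipped = count_flips(p, faces)
    sa = spherical_triangle_areas(p, faces)
    fa, _ = face_areas_normals(mesh.vertices, mesh.faces)
    ratio = (sa / sa.sum()) / np.maximum(fa / fa.sum(), 1e-300)
    # quasi-conformal distortion: singular-value ratio of the linear map
    # between each 3D source triangle and its (planar) spherical image
    v = mesh.vertices
    e1s = v[faces[:, 1]] - v[faces[:, 0]]
    e2s = v[faces[:, 2]] - v[faces[:, 0]]
    e1t = p[faces[:, 1]] - p[faces[:, 0]]
    e2t = p[faces[:, 2]] - p[faces[:, 0]]

    def to2d(e1, e2):
        x1 = np.linalg.norm(e1, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = e1 / np.maximum(x1[:, None], 1e-300)
        x2 = np.einsum("ij,ij->i", e2, u)
        y2 = np.linalg.norm(e2 - x2[:, None] * u, axis=1)
        return x1, x2, y2

    x1s, x2s, y2s = to2d(e1s, e2s)
    x1t, x2t, y2t = to2d(e1t, e2t)
    # J maps (x1s,0)->(x1t,0), (x2s,y2s)->(x2t,y2t)
    with np.errstate(invalid="ignore", divide="ignore"):
        a11 = x1t / x1s
        a21 = np.zeros_like(a11)
        a12 = (x2t - a11 * x2s) / np.maximum(y2s, 1e-300)
        a22 = y2t / np.maximum(y2s, 1e-300)
    J2 = np.stack(
        [
            np.stack([a11, a12], axis=-1),
            np.stack([a21, a22], axis=-1),
        ],
        axis=1,
    )
    s = np.linalg.svd(J2, compute_uv=False)
    dist = s[:, 0] / np.maximum(s[:, 1], 1e-300)
    return MapQuality(n_flipped=n_flipped, area_ratio=ratio, conformal_distortion=dist)


# ---------------------------------------------------------------------------
# point location / interpolation on the sphere
# ---------------------------------------------------------------------------


class SphereLocator:
    """Locate query directions in a spherical triangulation.

    KD-tree over face centroids with candidate containment testing (sign of
    the three determinants), exhaustive fallback.  Ties broken toward the
    lower face index.  Requires a flip-free map.
    """

    def __init__(self, positions: np.ndarray, faces: np.ndarray):
        self.p = np.asarray(positions, dtype=np.float64)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.orient = 1.0 if (face_orientations(self.p, self.faces) >= 0).mean() >= 0.5 else -1.0
        centroids = _normalize_rows(self.p[self.faces].mean(axis=1))
        self.tree = cKDTree(centroids)
        self._a = self.p[self.faces[:, 0]]
        self._b = self.p[self.faces[:, 1]]
        self._c = self.p[self.faces[:, 2]]

    def _signed(self, q: np.ndarray, fidx: np.ndarray):
        """Min signed determinant of q against the three oriented edges."""
        a, b, c = self._a[fidx], self._b[fidx], self._c[fidx]
        d1 = np.einsum("...j,...j->...", np.cross(a, b), q) * self.orient
        d2 = np.einsum("...j,...j->...", np.cross(b, c), q) * self.orient
        d3 = np.einsum("...j,...j->...", np.cross(c, a), q) * self.orient
        return np.minimum(np.minimum(d1, d2), d3)

    def locate(self, queries: np.ndarray, k: int = 16, tol: float = 1e-12):
        """Return (face_indices, barycentric_weights (n,3)) for unit queries."""
        q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
        norms = np.linalg.norm(q, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            warnings.warn("queries normalized to unit length", RuntimeWarning, stacklevel=2)
        q = q / norms[:, None]
        n = len(q)
        face_out = -np.ones(n, dtype=np.int64)
        kk = min(k, len(self.faces))
        _, cand = self.tree.query(q, k=kk)
        cand = np.atleast_2d(cand)
        # candidate test, preferring the lowest face index among containers
        sd = self._signed(q[:, None, :], cand)  # (n, kk)
        ok = sd >= -tol
        any_ok = ok.any(axis=1)
        rows = np.nonzero(any_ok)[0]
        for i in rows:
            hits = cand[i][ok[i]]
            face_out[i] = hits.min()
        missing = np.nonzero(face_out < 0)[0]
        if len(missing):
            # exhaustive fallback: face with maximal minimum signed det
            all_f = np.arange(len(self.faces))
            for i in missing:
                sdi = self._signed(q[i][None, :], all_f)
                best = int(np.argmax(sdi))
                if sdi[best] < -1e-6:
                    raise SphericalMapError(
                        "containment failure; the spherical map appears flipped"
                    )
                face_out[i] = best
        # barycentric weights: solve q ~ w_a a + w_b b + w_c c
        tri = np.stack(
            [self._a[face_out], self._b[face_out], self._c[face_out]], axis=-1
        )  # (n, 3, 3) columns are a,b,c
        w = np.linalg.solve(tri + 1e-15 * np.eye(3), q[..., None])[..., 0]
        w = np.clip(w, 0.0, None)
        w = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
        return face_out, w

    def interpolate(self, queries: np.ndarray, values: np.ndarray):
        """Barycentric interpolation of per-vertex values at query directions."""
        fidx, w = self.locate(queries)
        vals = values[self.faces[fidx]]  # (n, 3, ...)
        if vals.ndim == 2:
            return np.einsum("nk,nk->n", w, vals)
        return np.einsum("nk,nkj->nj", w, vals)


def sphere_lookup(sphmap: SphericalMap, query: np.ndarray):
    """Locate a single unit direction; returns (face index, weights)."""
    loc = SphereLocator(sphmap.sphere_positions, sphmap.faces)
    f, w = loc.locate(np.atleast_2d(query))
    return int(f[0]), w[0]
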