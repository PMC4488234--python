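"""Synthetic 3dMD-like face scans with known ground truth.

Real stereophotogrammetric face scans cannot be bundled, so every stage is
exercised on procedurally generated stand-ins: a template head built from
a subdivided icosphere (radius 80 mm) with Gaussian radial features (nose,
eye sockets, brows, chin, lips, cheeks), procedural per-vertex skin/lip/eye
colouring, ten named anatomical curves, and per-subject variation drawn
from a seeded population model:

* feature height and angular-position jitter (smooth shape variability),
* a global similarity transform (log-scale, rotation, translation pose
  jitter),
* channel-correlated colour (hue/luminance) jitter, which makes texture
  matching a genuine multi-modal problem,
* optional scan defects: punched holes, non-manifold fin triangles, a
  floating island component, and an open neck (polar cap removal).

All subjects share the template's vertex indexing, so ground-truth
cross-subject correspondence is vertex identity — registration error can
be measured exactly.  Generation is deterministic in (seed, subject_index).

What this emulates — and does not: smooth skin-like geometry with
localized features and per-vertex colour at scan-like scale.  It does not
model hair, specular highlights, expression change, or scanner-specific
noise spectra; conclusions from these fixtures are about the pipeline's
correctness, not about performance on any particular scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import trimesh

from .mesh import ColoredMesh, CurveSet


@dataclass
class Feature:
    """One Gaussian radial feature on the template head."""

    direction: np.ndarray  # unit vector, bump centre
    width: float  # angular width sigma (radians)
    height: float  # mm, negative = depression
    tint: Optional[np.ndarray] = None  # additive RGB within the bump support


def _u(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


def default_features() -> dict:
    """Nose / eyes / brows / chin / lips / cheeks on the +z hemisphere."""
    return {
        "nose": Feature(_u([0.0, -0.10, 1.0]), 0.22, 12.0),
        "eye_left": Feature(_u([-0.38, 0.28, 1.0]), 0.14, -3.0, np.array([-0.25, -0.22, -0.12])),
        "eye_right": Feature(_u([0.38, 0.28, 1.0]), 0.14, -3.0, np.array([-0.25, -0.22, -0.12])),
        "brow_left": Feature(_u([-0.38, 0.52, 1.0]), 0.12, 2.0, np.array([-0.35, -0.30, -0.25])),
        "brow_right": Feature(_u([0.38, 0.52, 1.0]), 0.12, 2.0, np.array([-0.35, -0.30, -0.25])),
        "chin": Feature(_u([0.0, -0.85, 0.95]), 0.20, 6.0),
        "lips": Feature(_u([0.0, -0.52, 1.0]), 0.13, 2.5, np.array([0.12, -0.18, -0.12])),
        "cheek_left": Feature(_u([-0.55, -0.18, 0.95]), 0.28, 3.0, np.array([0.05, -0.02, -0.02])),
        "cheek_right": Feature(_u([0.55, -0.18, 0.95]), 0.28, 3.0, np.array([0.05, -0.02, -0.02])),
    }


@dataclass
class FacePopulationSpec:
    """Population model for synthetic cohorts (all jitters are SDs)."""

    n_subjects: int = 10
    base_resolution: int = 3  # icosphere subdivision level, >= 3
    base_radius: float = 80.0  # mm
    features: dict = field(default_factory=default_features)
    shape_height_jitter: float = 1.0  # mm
    shape_position_jitter: float = 0.02  # radians
    global_scale_jitter: float = 0.02  # SD of log-scale
    pose_rotation_jitter: float = 0.10  # radians
    pose_translation_jitter: float = 5.0  # mm
    hue_jitter: float = 0.04
    n_holes: int = 0
    hole_angle: float = 0.12  # radians, angular hole radius
    n_fins: int = 0
    add_island: bool = False
    open_neck: bool = False  # delete the -z polar cap (open scan boundary)
    neck_angle: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.base_resolution < 3:
            raise ValueError("base_resolution must be >= 3 (>= 642 vertices)")
        for name in ("shape_height_jitter", "shape_position_jitter",
                     "global_scale_jitter", "pose_rotation_jitter",
                     "pose_translation_jitter", "hue_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


_SKIN = np.array([0.80, 0.62, 0.52])


def _template_directions(spec: FacePopulationSpec):
    ico = trimesh.creation.icosphere(spec.base_resolution)
    return np.asarray(ico.vertices, dtype=np.float64), np.asarray(ico.faces, dtype=np.int64)


def _rotate_small(d: np.ndarray, rng: np.random.Generator, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return d
    rv = rng.normal(0.0, sigma, 3)
    theta = np.linalg.norm(rv)
    if theta < 1e-15:
        return d
    k = rv / theta
    return d * np.cos(theta) + np.cross(k, d) * np.sin(theta) + k * np.dot(k, d) * (1 - np.cos(theta))


def _radial_field(dirs: np.ndarray, feats: dict, radius: float) -> np.ndarray:
    r = np.full(len(dirs), radius)
    for f in feats.values():
        ang = np.arccos(np.clip(dirs @ f.direction, -1.0, 1.0))
        r += f.height * np.exp(-0.5 * (ang / f.width) ** 2)
    return r


def _color_field(dirs: np.ndarray, feats: dict) -> np.ndarray:
    col = np.tile(_SKIN, (len(dirs), 1))
    for f in feats.values():
        if f.tint is None:
            continue
        ang = np.arccos(np.clip(dirs @ f.direction, -1.0, 1.0))
        col += np.outer(np.exp(-0.5 * (ang / f.width) ** 2), f.tint)
    return np.clip(col, 0.0, 1.0)


def _rotation_matrix(rv: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(rv)
    if theta < 1e-15:
        return np.eye(3)
    k = rv / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


# ten anatomical curves, mirroring a manual tracing protocol
_CURVE_DEFS = {
    "midline": [(0.0, 0.65), (0.0, 0.35), (0.0, 0.0), (0.0, -0.35), (0.0, -0.7), (0.0, -0.95)],
    "nose_bridge": [(0.0, 0.30), (0.0, 0.15), (0.0, 0.0), (0.0, -0.12)],
    "left_eye_rim": "circle:eye_left:0.17",
    "right_eye_rim": "circle:eye_right:0.17",
    "left_nostril": [(-0.16, -0.18), (-0.20, -0.26), (-0.12, -0.32)],
    "right_nostril": [(0.16, -0.18), (0.20, -0.26), (0.12, -0.32)],
    "upper_lip": [(-0.22, -0.45), (0.0, -0.40), (0.22, -0.45)],
    "lower_lip": [(-0.22, -0.60), (0.0, -0.66), (0.22, -0.60)],
    "left_jaw": [(-0.62, 0.05), (-0.55, -0.35), (-0.35, -0.70), (-0.12, -0.92)],
    "right_jaw": [(0.62, 0.05), (0.55, -0.35), (0.35, -0.70), (0.12, -0.92)],
}


def _anchor_to_dir(x: float, y: float) -> np.ndarray:
    return _u([x, y, 1.0])


def _slerp_chain(anchors, n_per_seg: int = 8) -> np.ndarray:
    pts = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
        for t in np.linspace(0.0, 1.0, n_per_seg, endpoint=False):
            if omega < 1e-12:
                pts.append(a)
            else:
                pts.append(
                    (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)
                )
    pts.append(anchors[-1])
    return np.asarray(pts)


def template_curves(spec: FacePopulationSpec) -> CurveSet:
    """Ten named curves as template vertex-index polylines."""
    dirs, _ = _template_directions(spec)
    feats = spec.features
    curves = {}
    for name, defn in _CURVE_DEFS.items():
        if isinstance(defn, str):
            _, feat, rad = defn.split(":")
            c = feats[feat].direction
            rad = float(rad)
            # small circle around the feature centre
            e1 = _u(np.cross(c, [0.0, 1.0, 0.0]))
            e2 = np.cross(c, e1)
            ts = np.linspace(0.0, 2 * np.pi, 13)
            sample = np.array(
                [np.cos(rad) * c + np.sin(rad) * (np.cos(t) * e1 + np.sin(t) * e2) for t in ts]
            )
        else:
            anchors = [_anchor_to_dir(x, y) for x, y in defn]
            sample = _slerp_chain(anchors)
        idx = np.argmax(sample @ dirs.T, axis=1)  # nearest vertex by direction
        dedup = [int(idx[0])]
        for i in idx[1:]:
            if int(i) != dedup[-1]:
                dedup.append(int(i))
        curves[name] = dedup
    cs = CurveSet(curves)
    cs.validate()
    return cs


def make_face(spec: FacePopulationSpec, subject_index: int, pose_seed: Optional[int] = None):
    """One subject: (ColoredMesh, CurveSet, ground-truth vertex map).

    Deterministic in (spec.seed, subject_index); ``pose_seed`` re-draws the
    pose and colour jitter while keeping the subject's shape parameters
    (the "same patient, new session" scenario).  The ground-truth
    correspondence to the template is vertex identity.
    """
    spec.validate()
    rng_shape = np.random.default_rng([abs(spec.seed), subject_index, 11])
    rng_pose = np.random.default_rng(
        [abs(pose_seed if pose_seed is not None else spec.seed), subject_index, 23]
    )
    dirs, faces = _template_directions(spec)
    feats = {}
    for name, f in spec.features.items():
        feats[name] = Feature(
            direction=_rotate_small(f.direction, rng_shape, spec.shape_position_jitter),
            width=f.width,
            height=f.height + rng_shape.normal(0.0, spec.shape_height_jitter),
            tint=f.tint,
        )
    r = _radial_field(dirs, feats, spec.base_radius)
    vertices = dirs * r[:, None]
    color = _color_field(dirs, feats)
    # channel-correlated colour jitter: luminance plus a red/blue hue shift
    lum = rng_pose.normal(0.0, spec.hue_jitter)
    hue = rng_pose.normal(0.0, spec.hue_jitter)
    gains = (1.0 + lum) * np.array([1.0 + hue, 1.0, 1.0 - hue])
    color = np.clip(color * gains, 0.0, 1.0)
    # pose: similarity transform
    s = float(np.exp(rng_pose.normal(0.0, spec.global_scale_jitter)))
    R = _rotation_matrix(rng_pose.normal(0.0, spec.pose_rotation_jitter, 3))
    t = rng_pose.normal(0.0, spec.pose_translation_jitter, 3)
    vertices = s * vertices @ R.T + t
    mesh = ColoredMesh.from_arrays(vertices, faces, color=color)
    curves = template_curves(spec)
    gt = np.arange(len(vertices))
    return mesh, curves, gt


def inject_defects(mesh: ColoredMesh, spec: FacePopulationSpec,
                   rng: Optional[np.random.Generator] = None) -> ColoredMesh:
    """Punch holes, attach non-manifold fins, optionally add an island/neck.

    Holes avoid the facial (+z) region so the anatomy used for matching
    survives, mimicking occlusion artefacts at the scan periphery.
    """
    if rng is None:
        rng = np.random.default_rng(abs(spec.seed))
    out = mesh.copy()
    center = out.vertices.mean(axis=0)
    dirs = out.vertices - center
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if spec.open_neck:
        fc = dirs[out.faces].mean(axis=1)
        fc /= np.linalg.norm(fc, axis=1, keepdims=True)
        keep = np.arccos(np.clip(fc @ np.array([0.0, 0.0, -1.0]), -1, 1)) > spec.neck_angle
        out = ColoredMesh(out.vertices, out.faces[keep], out.color, out.filler)
    for _ in range(spec.n_holes):
        # rear/side hemisphere only
        while True:
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            if d[2] < 0.2:
                break
        fc = dirs[out.faces].mean(axis=1)
        fc /= np.linalg.norm(fc, axis=1, keepdims=True)
        drop = np.arccos(np.clip(fc @ d, -1, 1)) <= spec.hole_angle
        if drop.all():
            raise ValueError("requested hole larger than the mesh")
        if drop.any():
            out = ColoredMesh(out.vertices, out.faces[~drop], out.color, out.filler)
    for _ in range(spec.n_fins):
        fi = int(rng.integers(out.n_faces))
        a, b = int(out.faces[fi, 0]), int(out.faces[fi, 1])
        apex = out.vertices[[a, b]].mean(axis=0) + rng.normal(0, 1, 3) + dirs[a] * 15.0
        vid = out.n_vertices
        out = ColoredMesh(
            np.vstack([out.vertices, apex]),
            np.vstack([out.faces, [[a, b, vid]]]),
            np.vstack([out.color, [[0.5, 0.5, 0.5]]]),
            np.concatenate([out.filler, [False]]),
        )
    if spec.add_island:
        tet = trimesh.creation.icosphere(0, radius=5.0)
        off = out.vertices.mean(axis=0) + np.array([0.0, 0.0, -3.0 * spec.base_radius])
        vid = out.n_vertices
        out = ColoredMesh(
            np.vstack([out.vertices, tet.vertices + off]),
            np.vstack([out.faces, tet.faces + vid]),
            np.vstack([out.color, np.full((len(tet.vertices), 3), 0.5)]),
            np.concatenate([out.filler, np.zeros(len(tet.vertices), dtype=bool)]),
        )
    return out


def make_cohort(spec: FacePopulationSpec, pose_seed: Optional[int] = None,
                with_defects: bool = False):
    """A population of subjects plus the analytic population mean.

    Returns (subjects, template, gt) where subjects is a list of
    (mesh, curves) tuples, template is the jitter-free population mean
    shape, and gt the (identity) template correspondence.  ``pose_seed``
    regenerates the same subjects at a later session (new pose and colour
    draw, identical shape parameters).
    """
    if spec.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    subjects = []
    rng_defect = np.random.default_rng([abs(spec.seed), 77])
    for i in range(spec.n_subjects):
        mesh, curves, gt = make_face(spec, i, pose_seed=pose_seed)
        if with_defects:
            mesh = inject_defects(mesh, spec, rng_defect)
        subjects.append((mesh, curves))
    template = population_mean(spec)
    return subjects, template, np.arange(template.n_vertices)


def population_mean(spec: FacePopulationSpec) -> ColoredMesh:
    """The jitter-free template (the analytic population mean shape)."""
    dirs, faces = _template_directions(spec)
    r = _radial_field(dirs, spec.features, spec.base_radius)
    return ColoredMesh.from_arrays(dirs * r[:, None], faces, color=_color_field(dirs, spec.features))
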