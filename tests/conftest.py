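import numpy as np
import pytest
import trimesh

from morphoface import (
    ColoredMesh,
    FacePopulationSpec,
    Subject,
    make_face,
    spherical_parameterize,
)


def icosphere_mesh(subdiv: int = 3, radius: float = 1.0, seed=None) -> ColoredMesh:
    ico = trimesh.creation.icosphere(subdiv, radius=radius)
    color = None
    if seed is not None:
        color = np.random.default_rng(seed).random((len(ico.vertices), 3))
    return ColoredMesh.from_arrays(ico.vertices, ico.faces, color=color)


def punch_hole(mesh: ColoredMesh, center, angle: float) -> ColoredMesh:
    """Delete the faces whose centroid direction lies within `angle` of center."""
    c = np.asarray(center, dtype=float)
    c /= np.linalg.norm(c)
    ctr = mesh.vertices.mean(axis=0)
    fc = mesh.vertices[mesh.faces].mean(axis=1) - ctr
    fc /= np.linalg.norm(fc, axis=1, keepdims=True)
    keep = np.arccos(np.clip(fc @ c, -1, 1)) > angle
    return ColoredMesh(mesh.vertices.copy(), mesh.faces[keep],
                       mesh.color.copy(), mesh.filler.copy())


@pytest.fixture(scope="session")
def unit_sphere():
    return icosphere_mesh(3)


@pytest.fixture(scope="session")
def colored_sphere():
    return icosphere_mesh(3, seed=0)


@pytest.fixture(scope="session")
def face_subject():
    """One synthetic face with its spherical map (session-cached: slow)."""
    spec = FacePopulationSpec(seed=0)
    mesh, curves, _ = make_face(spec, 0)
    sphmap = spherical_parameterize(mesh)
    return Subject(mesh=mesh, sphmap=sphmap, curves=curves)


@pytest.fixture(scope="session")
def pose_pair():
    """Two same-shape subjects differing only in pose and colour gains."""
    spec = FacePopulationSpec(seed=1, shape_height_jitter=0.0,
                              shape_position_jitter=0.0)
    out = []
    for i in range(2):
        mesh, curves, _ = make_face(spec, i)
        out.append(Subject(mesh=mesh, sphmap=spherical_parameterize(mesh),
                           curves=curves))
    return out
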