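"""Topology correction: non-manifold repair, hole closure, smoothing."""

import numpy as np
import pytest
import trimesh

from morphoface import (
    ColoredMesh,
    FacePopulationSpec,
    close_boundaries,
    diagnose,
    inject_defects,
    make_face,
    remove_nonmanifold,
    sew_boundary,
    smooth,
)
from morphoface.mesh import face_areas_normals, total_area
from morphoface.topology import TopologyError, correct, relax_patch

from conftest import icosphere_mesh, punch_hole


class TestRemoveNonmanifold:
    def test_three_triangles_keep_two_largest(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 2], [0, -0.1, 0]], float)
        f = np.array([[0, 1, 2], [1, 0, 3], [0, 1, 4]])  # third is smallest
        # all three share edge (0,1); the smallest-area fin must go
        out = remove_nonmanifold(ColoredMesh.from_arrays(v, f))
        d = diagnose(out)
        assert len(d.nonmanifold_edges) == 0
        assert out.n_faces == 2

    def test_island_removal_keeps_larger_sphere(self):
        big = icosphere_mesh(2, radius=2.0)
        small = icosphere_mesh(2, radius=1.0)
        merged = ColoredMesh.from_arrays(
            np.vstack([big.vertices, small.vertices + [10, 0, 0]]),
            np.vstack([big.faces, small.faces + big.n_vertices]),
        )
        out = remove_nonmanifold(merged)
        assert out.n_vertices == big.n_vertices
        assert total_area(out) == pytest.approx(total_area(big))

    def test_idempotent_on_manifold(self, colored_sphere):
        out = remove_nonmanifold(colored_sphere)
        assert out.n_vertices == colored_sphere.n_vertices
        assert out.n_faces == colored_sphere.n_faces
        np.testing.assert_array_equal(out.color, colored_sphere.color)


class TestSewAndRelax:
    def test_fan_closure_of_triangle_boundary(self):
        m = ColoredMesh.from_arrays(np.eye(3), [[0, 1, 2]])
        loop = diagnose(m).boundary_loops[0]
        out, rec = sew_boundary(m, loop)
        d = diagnose(out)
        assert d.n_boundary_loops == 0
        assert out.n_vertices == 4 and out.n_faces == 4
        assert out.filler[3] and not out.filler[:3].any()

    def test_hole_closure_decrements_loop_count(self):
        holed = punch_hole(icosphere_mesh(3), [1, 0, 0], 0.3)
        holed = remove_nonmanifold(holed)
        before = diagnose(holed).n_boundary_loops
        loop = diagnose(holed).boundary_loops[0]
        out, _ = sew_boundary(holed, loop)
        assert diagnose(out).n_boundary_loops == before - 1

    def test_short_loop_rejected(self, unit_sphere):
        with pytest.raises(ValueError):
            sew_boundary(unit_sphere, [0, 1])

    def test_planar_boundary_relaxes_back_to_plane(self):
        # hexagonal fan in z=0 with the centroid pushed off-plane
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        rim = np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)
        v = np.vstack([rim, [[0, 0, 0.5]]])
        f = np.array([[k, (k + 1) % 6, 6] for k in range(6)])
        m = ColoredMesh.from_arrays(v, f)
        from morphoface.topology import PatchRecord

        rec = PatchRecord(source_loop=list(range(6)),
                          patch_faces=np.arange(6), patch_vertices=np.array([6]),
                          area_history=[])
        out = relax_patch(m, rec)
        assert abs(out.vertices[6, 2]) < 1e-8

    def test_relax_never_increases_area(self):
        holed = remove_nonmanifold(punch_hole(icosphere_mesh(3), [0, 0, 1], 0.3))
        loop = diagnose(holed).boundary_loops[0]
        sewn, rec = sew_boundary(holed, loop)
        a0 = face_areas_normals(sewn.vertices, sewn.faces[rec.patch_faces])[0].sum()
        relaxed = relax_patch(sewn, rec)
        a1 = face_areas_normals(relaxed.vertices, relaxed.faces[rec.patch_faces])[0].sum()
        assert a1 <= a0 + 1e-9

    def test_patch_without_interior_vertices_is_noop(self, unit_sphere):
        from morphoface.topology import PatchRecord

        rec = PatchRecord(source_loop=[0, 1, 2], patch_faces=np.array([0]),
                          patch_vertices=np.array([], dtype=int), area_history=[])
        out = relax_patch(unit_sphere, rec)
        np.testing.assert_array_equal(out.vertices, unit_sphere.vertices)


class TestCloseBoundaries:
    def test_open_neck_scan_becomes_spherical(self):
        spec = FacePopulationSpec(seed=2, open_neck=True)
        mesh, _, _ = make_face(spec, 0)
        mesh = inject_defects(mesh, spec)
        mesh = remove_nonmanifold(mesh)
        closed, recs = close_boundaries(mesh)
        d = diagnose(closed)
        assert d.euler_characteristic == 2
        assert d.n_boundary_loops == 0
        assert d.genus == 0
        assert len(recs) == 1

    def test_three_holes_three_monotone_patches(self):
        m = icosphere_mesh(3, radius=80.0)
        for c, a in ([1, 0, 0], 0.2), ([0, 1, 0], 0.18), ([0, 0, 1], 0.15):
            m = punch_hole(m, c, a)
        m = remove_nonmanifold(m)
        closed, recs = close_boundaries(m)
        assert len(recs) == 3
        for rec in recs:
            hist = np.asarray(rec.area_history)
            assert (np.diff(hist[1:]) <= 1e-9).all()
        assert diagnose(closed).n_boundary_loops == 0

    def test_already_closed_is_noop(self, colored_sphere):
        out, recs = close_boundaries(colored_sphere)
        assert recs == []
        np.testing.assert_array_equal(out.vertices, colored_sphere.vertices)

    def test_filler_flags_exactly_on_new_vertices(self):
        holed = remove_nonmanifold(punch_hole(icosphere_mesh(3), [0, 0, 1], 0.25))
        n_orig = holed.n_vertices
        closed, _ = close_boundaries(holed)
        assert not closed.filler[:n_orig].any()
        assert closed.filler[n_orig:].all()

    def test_full_correction_idempotent(self):
        spec = FacePopulationSpec(seed=4, n_holes=2, n_fins=1, add_island=True)
        mesh, _, _ = make_face(spec, 0)
        mesh = inject_defects(mesh, spec)
        once, _, _ = correct(mesh)
        twice, _, _ = correct(once)
        assert twice.n_vertices == once.n_vertices
        assert twice.n_faces == once.n_faces
        np.testing.assert_allclose(twice.vertices, once.vertices)


class TestSmooth:
    def test_noise_reduction_on_sphere(self):
        rng = np.random.default_rng(0)
        m = icosphere_mesh(3)
        noisy = m.copy()
        noisy.vertices = m.vertices * (1 + 0.01 * rng.standard_normal(m.n_vertices))[:, None]
        sm = smooth(noisy, iterations=10, lam=0.5)
        r_pre = np.std(np.linalg.norm(noisy.vertices, axis=1))
        r_post = np.std(np.linalg.norm(sm.vertices, axis=1))
        assert r_post < r_pre

    def test_zero_iterations_is_identity(self, colored_sphere):
        out = smooth(colored_sphere, iterations=0)
        np.testing.assert_array_equal(out.vertices, colored_sphere.vertices)

    def test_connectivity_and_flags_preserved(self, colored_sphere):
        out = smooth(colored_sphere, iterations=5)
        assert out.n_vertices == colored_sphere.n_vertices
        np.testing.assert_array_equal(out.faces, colored_sphere.faces)
        np.testing.assert_array_equal(out.filler, colored_sphere.filler)


class TestDefectRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_defects_then_correction_restores_sphere_topology(self, seed):
        spec = FacePopulationSpec(seed=seed, n_holes=2, n_fins=2, add_island=True)
        mesh, _, _ = make_face(spec, 0)
        broken = inject_defects(mesh, spec,
                                rng=np.random.default_rng(seed))
        fixed, _, report = correct(broken)
        d = diagnose(fixed)
        assert d.euler_characteristic == 2
        assert d.n_boundary_loops == 0
        assert d.is_manifold
        assert report["after"]["genus"] == 0
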