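"""ICP fusion, lesion tagging and Dice co-location."""

import itertools

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from atriascar import (
    LesionTagSet,
    RigidTransform,
    SurfaceMesh,
    coloc_pipeline,
    dsc,
    icp_rigid,
    tag_faces,
)

from oracles import dsc_formula


def _ellipsoid_mesh(radii=(28.0, 24.0, 21.0), subdivisions=2, center=(0.0, 0.0, 0.0)):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return SurfaceMesh(
        np.asarray(ico.vertices) * np.asarray(radii) + np.asarray(center),
        np.asarray(ico.faces),
    )


def _rot(axis, angle_deg):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * k @ k


class TestRigidTransform:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_apply_then_invert_is_identity(self, rng):
        t = RigidTransform(_rot([1, 2, 3], 33.0), np.array([5.0, -3.0, 2.0]))
        pts = rng.normal(0, 20, (50, 3))
        back = t.inverse().apply(t.apply(pts))
        assert np.allclose(back, pts, atol=1e-6)


class TestIcp:
    def test_identical_meshes_give_identity(self):
        mesh = _ellipsoid_mesh()
        res = icp_rigid(mesh, mesh)
        assert res.mean_distance_mm == pytest.approx(0.0, abs=1e-9)
        assert res.transform.rotation_angle_deg == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(res.transform.translation_mm, 0.0, atol=1e-9)

    def test_recovers_known_transform(self):
        mesh = _ellipsoid_mesh()
        true = RigidTransform(_rot([0, 0, 1], 10.0), np.array([5.0, -3.0, 2.0]))
        target = SurfaceMesh(true.apply(mesh.vertices), mesh.faces)
        res = icp_rigid(mesh, target)
        err = res.transform.compose(true.inverse())
        assert err.rotation_angle_deg < 0.5
        assert res.mean_distance_mm < 0.5

    def test_recovers_rotation_under_vertex_jitter(self):
        mesh = _ellipsoid_mesh()
        true = RigidTransform(_rot([1, 1, 0], 5.0), np.array([2.0, 1.0, -4.0]))
        failures = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            verts = true.apply(mesh.vertices) + rng.normal(0, 1.0, mesh.vertices.shape)
            res = icp_rigid(mesh, SurfaceMesh(verts, mesh.faces))
            err = res.transform.compose(true.inverse())
            failures += err.rotation_angle_deg > 2.0
        assert failures == 0

    def test_invariant_under_common_rigid_motion(self):
        mesh = _ellipsoid_mesh()
        true = RigidTransform(_rot([0, 1, 0], 12.0), np.array([4.0, 4.0, -1.0]))
        target = SurfaceMesh(true.apply(mesh.vertices), mesh.faces)
        base = icp_rigid(mesh, target)
        common = RigidTransform(_rot([2, -1, 1], 25.0), np.array([-7.0, 3.0, 9.0]))
        res = icp_rigid(
            SurfaceMesh(common.apply(mesh.vertices), mesh.faces),
            SurfaceMesh(common.apply(target.vertices), target.faces),
        )
        # conjugated transform: T' = C T C^-1, compared through point action
        pts = mesh.vertices[::13]
        a = res.transform.apply(common.apply(pts))
        b = common.apply(base.transform.apply(pts))
        assert np.allclose(a, b, atol=1e-6)

    def test_collinear_correspondence_rejected(self):
        # rank-deficient vertex sets admit no unique rigid fit
        line = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        degenerate = SurfaceMesh(line, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="rank-deficient"):
            icp_rigid(degenerate, degenerate, init=RigidTransform.identity())


class TestTagFaces:
    def test_tag_at_centroid_marks_that_face(self):
        mesh = _ellipsoid_mesh()
        tags = LesionTagSet(mesh.face_centroids[[100]], range_mm=3.0)
        marked = tag_faces(mesh, tags)
        assert marked[100]

    def test_out_of_range_tag_marks_nothing(self):
        mesh = _ellipsoid_mesh()
        tags = LesionTagSet(np.array([[500.0, 500.0, 500.0]]), range_mm=3.0)
        assert not tag_faces(mesh, tags).any()

    def test_empty_tag_set_warns_all_false(self):
        mesh = _ellipsoid_mesh()
        with pytest.warns(UserWarning, match="empty"):
            marked = tag_faces(mesh, LesionTagSet(np.empty((0, 3))))
        assert not marked.any()

    def test_ring_of_tags_matches_all_pairs_oracle(self, rng):
        mesh = _ellipsoid_mesh()
        phi = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        band = np.stack(
            [28 * np.sin(1.1) * np.cos(phi), 24 * np.sin(1.1) * np.sin(phi), 21 * np.cos(1.1) * np.ones_like(phi)],
            axis=1,
        )
        tags = LesionTagSet(band, range_mm=3.0)
        marked = tag_faces(mesh, tags)
        # exhaustive all-pairs distance check
        expected = np.zeros(mesh.n_faces, dtype=bool)
        for f, c in enumerate(mesh.face_centroids):
            for p in band:
                if np.linalg.norm(c - p) <= 3.0:
                    expected[f] = True
                    break
        assert np.array_equal(marked, expected)


class TestDsc:
    def test_identical_disjoint_and_worked_cases(self):
        a = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        assert dsc(a, a).dsc == 1.0
        assert dsc(a, ~a).dsc == 0.0
        scar = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        lesion = np.array([0, 1, 1, 1, 0, 0], dtype=bool)
        assert dsc(scar, lesion).dsc == pytest.approx(2 * 2 / (3 + 3))

    def test_both_empty_defined_as_one_with_warning(self):
        empty = np.zeros(5, dtype=bool)
        with pytest.warns(UserWarning, match="empty"):
            assert dsc(empty, empty).dsc == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="equal length"):
            dsc(np.zeros(4, dtype=bool), np.zeros(5, dtype=bool))

    def test_all_subsets_of_six_faces_match_formula(self, rng):
        areas = rng.uniform(0.5, 3.0, 6)
        for bits_a in range(64):
            a = np.array([(bits_a >> i) & 1 for i in range(6)], dtype=bool)
            for bits_b in range(64):
                b = np.array([(bits_b >> i) & 1 for i in range(6)], dtype=bool)
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    got_c = dsc(a, b, weighting="count").dsc
                    got_a = dsc(a, b, areas=areas, weighting="area").dsc
                assert got_c == pytest.approx(dsc_formula(a, b, np.ones(6)), rel=1e-12)
                assert got_a == pytest.approx(dsc_formula(a, b, areas), rel=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_symmetry_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(30) < 0.4
        b = rng.random(30) < 0.4
        if not (a.any() or b.any()):
            a[0] = True
        assert dsc(a, b).dsc == dsc(b, a).dsc
        perm = rng.permutation(30)
        assert dsc(a[perm], b[perm]).dsc == pytest.approx(dsc(a, b).dsc, rel=1e-12)

    def test_shrinking_disjoint_lesion_subset_never_raises_dsc(self):
        # removing lesion faces that never overlap scar cannot increase DSC
        scar = np.array([1, 1, 0, 0, 0, 0], dtype=bool)
        full = np.array([0, 1, 1, 1, 1, 0], dtype=bool)
        d_full = dsc(scar, full).dsc
        for drop in itertools.combinations([2, 3, 4], 2):
            sub = full.copy()
            sub[list(drop)] = False
            assert dsc(scar, sub).dsc >= d_full - 1e-12


class TestColocPipeline:
    def test_identical_meshes_perfect_tags_give_unity(self):
        mesh = _ellipsoid_mesh()
        scar = np.zeros(mesh.n_faces, dtype=bool)
        scar[40:80] = True
        tags = LesionTagSet(mesh.face_centroids[scar], range_mm=0.5)
        res = coloc_pipeline(mesh, scar, mesh, tags)
        assert res.dsc_result.dsc == 1.0
        assert res.n_unmatched_cmr_faces == 0

    def test_antipodal_tags_give_zero(self):
        mesh = _ellipsoid_mesh()
        north = mesh.face_centroids[:, 2] > 15.0
        south = mesh.face_centroids[:, 2] < -15.0
        tags = LesionTagSet(mesh.face_centroids[south], range_mm=0.5)
        res = coloc_pipeline(mesh, north, mesh, tags)
        assert res.dsc_result.dsc == 0.0

    def test_registration_is_blind_to_scar(self):
        mesh = _ellipsoid_mesh()
        true = RigidTransform(_rot([0, 0, 1], 7.0), np.array([3.0, 1.0, -2.0]))
        eam = SurfaceMesh(true.apply(mesh.vertices), mesh.faces)
        tags = LesionTagSet(eam.face_centroids[:30], range_mm=3.0)
        scar_a = np.zeros(mesh.n_faces, dtype=bool)
        scar_a[:30] = True
        scar_b = ~scar_a
        ta = coloc_pipeline(mesh, scar_a, eam, tags).transform
        tb = coloc_pipeline(mesh, scar_b, eam, tags).transform
        assert np.allclose(ta.as_matrix(), tb.as_matrix(), atol=1e-12)

    def test_gross_scale_mismatch_errors(self):
        cmr = _ellipsoid_mesh(radii=(28.0, 24.0, 21.0))
        eam = _ellipsoid_mesh(radii=(9.0, 8.0, 7.0))
        tags = LesionTagSet(eam.face_centroids[:5], range_mm=3.0)
        scar = np.zeros(cmr.n_faces, dtype=bool)
        scar[0] = True
        with pytest.raises(ValueError, match="misregistration"):
            coloc_pipeline(cmr, scar, eam, tags)
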