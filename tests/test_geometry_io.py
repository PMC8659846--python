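import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from psiplace import (
    CuttingPlane,
    FiducialSet,
    MeshFormatError,
    RigidTransform,
    apply_transform,
    closest_points_on_mesh,
    compose,
    invert,
    load_mesh,
    save_mesh,
)

ASCII_STL_TRIANGLE = """solid tri
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 0 1 0
  endloop
endfacet
endsolid tri
"""


def _random_transform(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    return RigidTransform(R, rng.normal(scale=10.0, size=3))


class TestMeshIO:
    def test_single_triangle_ascii_stl(self, tmp_path):
        path = tmp_path / "tri.stl"
        path.write_text(ASCII_STL_TRIANGLE)
        mesh = load_mesh(path)
        assert len(mesh.vertices) == 3
        assert len(mesh.faces) == 1

    def test_save_load_round_trip_preserves_vertices(self, tmp_path, cylinder):
        path = tmp_path / "cyl.stl"
        save_mesh(cylinder, path)
        back = load_mesh(path)
        assert len(back.vertices) == len(cylinder.vertices)
        # STL stores float32: coordinates survive to that precision
        a = np.array(sorted(map(tuple, np.round(back.vertices, 4))))
        b = np.array(sorted(map(tuple, np.round(cylinder.vertices, 4))))
        np.testing.assert_allclose(a, b, atol=1e-3)

    def test_truncated_binary_stl_raises(self, tmp_path):
        path = tmp_path / "bad.stl"
        path.write_bytes(b"\x00" * 84 + b"\x01\x02\x03")  # header + garbage
        with pytest.raises(MeshFormatError):
            load_mesh(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(MeshFormatError):
            load_mesh(tmp_path / "nope.stl")

    def test_ply_round_trip(self, tmp_path, cylinder):
        path = tmp_path / "cyl.ply"
        save_mesh(cylinder, path)
        back = load_mesh(path)
        assert len(back.faces) == len(cylinder.faces)


class TestRigidTransform:
    def test_identity_leaves_points(self, rng):
        pts = rng.normal(size=(7, 3))
        np.testing.assert_allclose(apply_transform(RigidTransform.identity(), pts), pts)

    def test_quarter_turn_about_z(self):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        T = RigidTransform(R, np.zeros(3))
        np.testing.assert_allclose(T.apply([1.0, 0.0, 0.0]), [0.0, 1.0, 0.0], atol=1e-12)

    @given(st.integers(0, 500))
    @settings(max_examples=40, deadline=None)
    def test_rigidity_preserves_pairwise_distances(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=50.0, size=(8, 3))
        T = _random_transform(seed + 1)
        moved = T.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)

    def test_invert_identity_is_identity(self):
        inv = invert(RigidTransform.identity())
        np.testing.assert_allclose(inv.matrix, np.eye(4), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_compose_with_inverse_is_identity(self, seed):
        T = _random_transform(seed)
        np.testing.assert_allclose(compose(invert(T), T).matrix, np.eye(4), atol=1e-9)

    def test_z_rotations_compose_additively(self):
        def rz(deg):
            return RigidTransform(Rotation.from_euler("z", deg, degrees=True).as_matrix(),
                                  np.zeros(3))
        np.testing.assert_allclose(compose(rz(60), rz(30)).matrix, rz(90).matrix, atol=1e-12)

    def test_compose_applies_first_argument_last(self):
        # T1 = translate x+1, T2 = rotate 90deg about z: compose(T2, T1) maps
        # origin -> (1,0,0) -> (0,1,0)
        T1 = RigidTransform(np.eye(3), [1.0, 0.0, 0.0])
        T2 = RigidTransform(Rotation.from_euler("z", 90, degrees=True).as_matrix(), np.zeros(3))
        np.testing.assert_allclose(compose(T2, T1).apply([0.0, 0.0, 0.0]),
                                   [0.0, 1.0, 0.0], atol=1e-12)

    def test_rejects_non_orthonormal_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))

    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestCuttingPlane:
    def test_normal_is_normalized(self):
        p = CuttingPlane([0, 0, 0], [0, 0, 10.0])
        assert abs(np.linalg.norm(p.normal) - 1.0) < 1e-12

    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError):
            CuttingPlane([0, 0, 0], [0, 0, 0])

    def test_transformed_moves_origin_and_normal(self):
        T = _random_transform(3)
        p = CuttingPlane([1.0, 2.0, 3.0], [0, 0, 1])
        q = p.transformed(T)
        np.testing.assert_allclose(q.origin, T.apply(p.origin))
        np.testing.assert_allclose(q.normal, T.rotation @ p.normal)


class TestFiducialSet:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            FiducialSet(("a", "a"), [[0, 0, 0], [1, 1, 1]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FiducialSet(("a", "b", "c"), [[0, 0, 0], [1, 1, 1]])

    def test_csv_round_trip(self, tmp_path, rng):
        fs = FiducialSet(("p1", "p2", "p3"), rng.normal(size=(3, 3)), "bone")
        path = tmp_path / "fids.csv"
        fs.to_csv(path)
        back = FiducialSet.from_csv(path)
        assert back.labels == fs.labels
        np.testing.assert_allclose(back.points, fs.points)

    def test_reordered_like_matches_labels(self, rng):
        fs = FiducialSet(("a", "b", "c"), rng.normal(size=(3, 3)))
        other = FiducialSet(("c", "a", "b"), rng.normal(size=(3, 3)))
        re = fs.reordered_like(other)
        assert re.labels == other.labels
        np.testing.assert_allclose(re.points[1], fs.points[0])


class TestClosestPoint:
    def test_matches_per_triangle_brute_force(self, coarse_cylinder, rng):
        """Batch query equals an explicit loop over every triangle."""
        pts = rng.normal(scale=30.0, size=(20, 3))
        closest, dist = closest_points_on_mesh(coarse_cylinder, pts)
        tri = coarse_cylinder.triangles
        for p, c, d in zip(pts, closest, dist):
            best = np.inf
            for t in tri:
                # dense sample of the triangle as an independent lower-tech check
                w = np.random.default_rng(0).dirichlet(np.ones(3), size=400)
                cand = w @ t
                best = min(best, np.linalg.norm(cand - p, axis=1).min())
            assert d <= best + 1e-6
            assert abs(np.linalg.norm(c - p) - d) < 1e-9

    def test_on_surface_points_have_zero_distance(self, phantom, rng):
        fi = rng.integers(0, len(phantom.faces), size=15)
        bary = rng.dirichlet(np.ones(3), size=15)
        pts = np.einsum("ij,ijk->ik", bary, phantom.triangles[fi])
        _, dist = closest_points_on_mesh(phantom, pts)
        assert dist.max() < 1e-9
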