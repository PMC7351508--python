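import numpy as np
import pytest
from itertools import permutations

from shapereg import (
    DegenerateGeometryError,
    EmptyMeshError,
    MeshFormatError,
    ParameterError,
    PointCloud,
    RigidTransform,
    TopologyError,
    TriMesh,
    best_fit_rigid,
    center_align,
    grid_average_downsample,
    mesh_volume,
    mirror,
    read_stl,
    scale_to_volume,
    write_stl,
)

ASCII_TRIANGLE = """solid tri
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 0 1 0
  endloop
endfacet
endsolid tri
"""


class TestSTLIO:
    def test_binary_round_trip_cube(self, unit_cube, tmp_path):
        p = tmp_path / "cube.stl"
        write_stl(unit_cube, p, mode="binary")
        assert p.stat().st_size == 84 + 12 * 50
        back = read_stl(p)
        assert back.n_vertices == 8 and back.n_faces == 12
        assert set(map(tuple, back.vertices)) == set(map(tuple, unit_cube.vertices))
        assert mesh_volume(back) == pytest.approx(1.0, abs=1e-9)

    def test_ascii_round_trip(self, unit_cube, tmp_path):
        p = tmp_path / "cube_ascii.stl"
        write_stl(unit_cube, p, mode="ascii")
        back = read_stl(p)
        assert back.n_vertices == 8 and back.n_faces == 12
        assert mesh_volume(back) == pytest.approx(1.0, abs=1e-9)

    def test_ascii_single_triangle(self, tmp_path):
        p = tmp_path / "tri.stl"
        p.write_text(ASCII_TRIANGLE)
        mesh = read_stl(p)
        assert mesh.n_vertices == 3 and mesh.n_faces == 1

    def test_round_trip_is_float32_lossless(self, tmp_path, rng):
        verts = rng.normal(size=(4, 3)).astype(np.float32).astype(float)
        mesh = TriMesh(verts, [[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
        p = tmp_path / "tet.stl"
        write_stl(mesh, p)
        back = read_stl(p)
        assert set(map(tuple, back.vertices)) == set(map(tuple, verts))

    def test_truncated_binary_names_byte_offset(self, unit_cube, tmp_path):
        p = tmp_path / "cube.stl"
        write_stl(unit_cube, p)
        data = p.read_bytes()[:-30]
        q = tmp_path / "trunc.stl"
        q.write_bytes(data)
        with pytest.raises(MeshFormatError, match=rf"byte {len(data)}"):
            read_stl(q)

    def test_empty_write_rejected(self, tmp_path):
        mesh = TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(EmptyMeshError):
            write_stl(mesh, tmp_path / "empty.stl")


class TestMirror:
    def test_involution(self, unit_cube):
        twice = mirror(mirror(unit_cube, "y"), "y")
        np.testing.assert_array_equal(twice.vertices, unit_cube.vertices)
        np.testing.assert_array_equal(twice.faces, unit_cube.faces)

    @pytest.mark.parametrize("axis", ["x", "y", "z"])
    def test_volume_preserved(self, unit_cube, axis):
        assert mesh_volume(mirror(unit_cube, axis)) == pytest.approx(1.0, abs=1e-12)

    def test_chiral_shape_not_superimposable(self):
        """A scalene tetrahedron and its mirror image differ under every
        proper rotation (exhaustive search over vertex matchings with the
        best proper rotation for each)."""
        verts = np.array([[0.0, 0, 0], [3.1, 0, 0], [0.7, 2.3, 0], [1.3, 0.9, 1.7]])
        tet = TriMesh(verts, [[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        mir = mirror(tet, "x")
        a = tet.vertices - tet.vertices.mean(axis=0)
        best = np.inf
        for perm in permutations(range(4)):
            b = mir.vertices[list(perm)] - mir.vertices.mean(axis=0)
            u, _, vt = np.linalg.svd(b.T @ a)
            rot = u @ np.diag([1, 1, np.sign(np.linalg.det(u @ vt))]) @ vt
            best = min(best, np.linalg.norm(b @ rot - a))
        assert best > 0.1


class TestDownsample:
    def test_two_close_points_merge(self):
        cloud = PointCloud([[0, 0, 0], [0.1, 0, 0]])
        out = grid_average_downsample(cloud, 1.0)
        np.testing.assert_allclose(out.points, [[0.05, 0, 0]])

    def test_far_points_retained(self):
        cloud = PointCloud([[0, 0, 0], [5, 0, 0]])
        out = grid_average_downsample(cloud, 1.0)
        assert len(out) == 2

    def test_matches_brute_force_cell_centroids(self, rng):
        pts = rng.uniform(0, 10, size=(10000, 3))
        cell = 1.0
        out = grid_average_downsample(PointCloud(pts), cell)
        assert len(out) <= 1000
        # brute force: group points by their cell index
        idx = np.floor((pts - pts.min(axis=0)) / cell).astype(int)
        expected = {}
        for i, key in enumerate(map(tuple, idx)):
            expected.setdefault(key, []).append(pts[i])
        want = sorted(tuple(np.mean(v, axis=0)) for v in expected.values())
        got = sorted(map(tuple, out.points))
        np.testing.assert_allclose(got, want, atol=1e-12)
        # every output point lies inside its own cell bounds
        lo = pts.min(axis=0)
        cells = np.floor((out.points - lo) / cell)
        assert ((out.points >= lo + cells * cell - 1e-12)
                & (out.points <= lo + (cells + 1) * cell + 1e-12)).all()

    def test_bad_cell_size(self, small_cloud):
        with pytest.raises(ParameterError):
            grid_average_downsample(small_cloud, 0.0)


class TestCenterAlign:
    def test_centroid_moves_to_origin(self):
        cloud = PointCloud(np.array([[3.0, 4, 5], [3, 4, 5], [3, 4, 5], [3, 4, 5]]) +
                           np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]]))
        out = center_align(cloud)
        np.testing.assert_allclose(out.centroid, 0.0, atol=1e-9)

    def test_already_centered_unchanged(self, small_cloud):
        centered = center_align(small_cloud)
        again = center_align(centered)
        np.testing.assert_allclose(again.points, centered.points, atol=1e-12)

    def test_single_point(self):
        out = center_align(PointCloud([[1.0, 1, 1]]))
        np.testing.assert_allclose(out.points, [[0, 0, 0]])


class TestBestFitRigid:
    def test_recovers_known_transform(self, rng):
        src = PointCloud(rng.normal(size=(60, 3)) * 5)
        ang = np.deg2rad(10)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        truth = RigidTransform(rot, [1.0, 2.0, 3.0])
        tgt = PointCloud(truth.apply(src.points))
        est = best_fit_rigid(src, tgt)
        np.testing.assert_allclose(est.rotation, truth.rotation, atol=1e-6)
        np.testing.assert_allclose(est.translation, truth.translation, atol=1e-6)

    def test_identity_for_equal_clouds(self, small_cloud):
        est = best_fit_rigid(small_cloud, small_cloud)
        np.testing.assert_allclose(est.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(est.translation, 0.0, atol=1e-9)

    def test_error_never_worse_than_initial(self, rng):
        from scipy.spatial import cKDTree
        src = PointCloud(rng.normal(size=(50, 3)))
        tgt = PointCloud(rng.normal(size=(70, 3)) + 0.3)
        est = best_fit_rigid(src, tgt)
        tree = cKDTree(tgt.points)
        before = np.mean(tree.query(src.points)[0])
        after = np.mean(tree.query(est.apply(src.points))[0])
        assert after <= before + 1e-12

    def test_collinear_rejected(self):
        line = PointCloud(np.outer(np.arange(10.0), [1, 0, 0]))
        blob = PointCloud(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(DegenerateGeometryError):
            best_fit_rigid(line, blob)


class TestVolume:
    def test_unit_cube(self, unit_cube):
        assert mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("factor", [0.5, 2.0, 3.0])
    def test_cubic_scaling(self, unit_cube, factor):
        scaled = TriMesh(unit_cube.vertices * factor, unit_cube.faces)
        assert mesh_volume(scaled) == pytest.approx(factor ** 3, rel=1e-12)

    def test_icosphere_closed_form(self, icosphere):
        assert mesh_volume(icosphere) == pytest.approx(4 * np.pi / 3, rel=0.01)

    def test_open_mesh_rejected_with_boundary_edges(self):
        tri = TriMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        with pytest.raises(TopologyError, match="boundary"):
            mesh_volume(tri)


class TestScaleToVolume:
    def test_cube_to_volume_8(self, unit_cube):
        out = scale_to_volume(unit_cube, 8.0)
        assert mesh_volume(out) == pytest.approx(8.0, rel=1e-6)
        span = out.vertices.max(axis=0) - out.vertices.min(axis=0)
        np.testing.assert_allclose(span, 2.0, rtol=1e-9)

    def test_scaling_to_own_volume_is_identity(self, icosphere):
        out = scale_to_volume(icosphere, mesh_volume(icosphere))
        np.testing.assert_allclose(out.vertices, icosphere.vertices, atol=1e-9)

    def test_centroid_preserved(self, unit_cube):
        out = scale_to_volume(unit_cube, 27.0)
        np.testing.assert_allclose(out.vertices.mean(axis=0),
                                   unit_cube.vertices.mean(axis=0), atol=1e-9)
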