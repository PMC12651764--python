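"""OBJ parsing, deterministic surface sampling, unit-sphere normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prepscore import geometry
from prepscore.geometry import (
    DegenerateCloudError,
    FaceIndexError,
    NoFacesError,
    PointCloud,
    PointCloudIOError,
    SamplerConfig,
    TriangleMesh,
    ZeroAreaError,
    normalize,
    read_obj,
    read_point_cloud,
    sample_point_cloud,
    write_point_cloud,
)


class TestReadObj:
    def test_minimal_obj(self, tmp_path):
        p = tmp_path / "t.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        mesh = read_obj(p)
        assert mesh.vertices.shape == (3, 3)
        assert mesh.faces.shape == (1, 3)
        assert mesh.source_id == "t"

    def test_quad_fan_triangulated(self, tmp_path):
        p = tmp_path / "q.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        mesh = read_obj(p)
        assert mesh.faces.shape == (2, 3)
        np.testing.assert_array_equal(mesh.faces, [[0, 1, 2], [0, 2, 3]])

    def test_normals_textures_materials_ignored(self, tmp_path):
        bare = tmp_path / "bare.obj"
        body = "v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n"
        bare.write_text(body)
        decorated = (
            "mtllib x.mtl\no tooth\nvn 0 0 1\nvt 0 0\nusemtl enamel\ns off\n"
            "v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1/1/1 2/1/1 3/1/1\n"
        )
        p2 = tmp_path / "deco.obj"
        p2.write_text(decorated)
        a, b = read_obj(bare), read_obj(p2)
        np.testing.assert_allclose(a.vertices, b.vertices)
        np.testing.assert_array_equal(a.faces, b.faces)

    def test_negative_indices_resolve_relative(self, tmp_path):
        p = tmp_path / "n.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf -3 -2 -1\n")
        np.testing.assert_array_equal(read_obj(p).faces, [[0, 1, 2]])

    def test_zero_area_faces_dropped(self, tmp_path):
        p = tmp_path / "z.obj"
        p.write_text(
            "v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\nf 1 1 2\n"  # second face degenerate
        )
        assert read_obj(p).faces.shape == (1, 3)

    def test_named_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_obj(tmp_path / "absent.obj")
        p = tmp_path / "bad_idx.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 9\n")
        with pytest.raises(FaceIndexError):
            read_obj(p)
        p2 = tmp_path / "no_faces.obj"
        p2.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\n")
        with pytest.raises(NoFacesError):
            read_obj(p2)


class TestSampling:
    def test_single_triangle_barycentric_containment(self, unit_triangle):
        pc = sample_point_cloud(unit_triangle, SamplerConfig(n_points=500, seed=3))
        x, y, z = pc.points.T
        assert np.allclose(z, 0)
        assert np.all(x >= -1e-12) and np.all(y >= -1e-12)
        assert np.all(x + y <= 1 + 1e-12)

    def test_exact_point_count_and_determinism(self, tetra_mesh):
        cfg = SamplerConfig(n_points=1234, seed=9)
        a = sample_point_cloud(tetra_mesh, cfg)
        b = sample_point_cloud(tetra_mesh, cfg)
        assert a.n_points == 1234
        assert np.array_equal(a.points, b.points)  # bit-identical

    def test_different_seed_different_points(self, tetra_mesh):
        a = sample_point_cloud(tetra_mesh, SamplerConfig(n_points=100, seed=1))
        b = sample_point_cloud(tetra_mesh, SamplerConfig(n_points=100, seed=2))
        assert not np.array_equal(a.points, b.points)

    def test_area_weighting_9_to_1(self, two_face_mesh):
        """Counts per face follow a binomial with p = 0.9 (3-sigma band)."""
        n = 100_000
        pc = sample_point_cloud(two_face_mesh, SamplerConfig(n_points=n, seed=11))
        on_big = np.count_nonzero(pc.points[:, 0] < 9.0)  # faces are disjoint in x
        p = 0.9
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(on_big - n * p) < 3 * sigma

    def test_chi_square_area_uniformity(self):
        """Per-face counts match area proportions on a 4-face mesh."""
        mesh = TriangleMesh(
            vertices=np.array(
                [[0, 0, 0], [1, 0, 0], [0, 1, 0],
                 [5, 0, 0], [7, 0, 0], [5, 2, 0],
                 [20, 0, 0], [23, 0, 0], [20, 3, 0],
                 [40, 0, 0], [44, 0, 0], [40, 4, 0]], dtype=float
            ),
            faces=np.arange(12).reshape(4, 3),
            source_id="four",
        )
        n = 60_000
        pc = sample_point_cloud(mesh, SamplerConfig(n_points=n, seed=5))
        areas = mesh.face_areas()
        expected = n * areas / areas.sum()
        # assign points to faces by x-range (faces disjoint in x)
        edges = [0, 4.9, 19.9, 39.9, np.inf]
        counts = np.histogram(pc.points[:, 0], bins=edges)[0]
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        # df = 3; 3-sigma-equivalent quantile
        from scipy.stats import chi2 as chi2_dist

        assert chi2 < chi2_dist(df=3).ppf(0.9973)

    def test_zero_area_mesh_raises(self):
        mesh = TriangleMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]),
            np.array([[0, 1, 2]]),
            source_id="flat",
        )
        with pytest.raises(ZeroAreaError):
            sample_point_cloud(mesh, SamplerConfig(n_points=10, seed=0))


class TestNormalize:
    def test_two_point_hand_case(self):
        pc = PointCloud(np.array([[0.0, 0, 0], [2, 0, 0]]))
        out = normalize(pc)
        np.testing.assert_allclose(out.points, [[-1, 0, 0], [1, 0, 0]], atol=1e-12)

    def test_idempotent(self, tetra_mesh):
        pc = sample_point_cloud(tetra_mesh, SamplerConfig(n_points=200, seed=1))
        once = normalize(pc)
        twice = normalize(once)
        np.testing.assert_allclose(once.points, twice.points, atol=1e-9)

    def test_invariants_after_normalization(self, tetra_mesh):
        pc = normalize(sample_point_cloud(tetra_mesh, SamplerConfig(n_points=500, seed=2)))
        assert np.linalg.norm(pc.points.mean(axis=0)) <= 1e-6
        r = np.linalg.norm(pc.points, axis=1).max()
        assert 1 - 1e-6 <= r <= 1 + 1e-6
        assert pc.is_normalized

    def test_similarity_invariance(self, tetra_mesh):
        """Translation + uniform scaling of the mesh leaves the normalized
        cloud unchanged (same source id, same seed)."""
        cfg = SamplerConfig(n_points=2000, seed=4)
        base = normalize(sample_point_cloud(tetra_mesh, cfg))
        moved = tetra_mesh.transformed(translation=(5, 5, 5), scale=3.0)
        other = normalize(sample_point_cloud(moved, cfg))
        np.testing.assert_allclose(base.points, other.points, atol=1e-6)

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateCloudError):
            normalize(PointCloud(np.ones((5, 3))))


@settings(max_examples=20, derandomize=True, deadline=None)
@given(
    st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50),
    st.floats(0.01, 100.0),
)
def test_normalization_similarity_invariance_property(tx, ty, tz, scale):
    mesh = TriangleMesh(
        vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        faces=np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]]),
        source_id="prop",
    )
    cfg = SamplerConfig(n_points=256, seed=7)
    base = normalize(sample_point_cloud(mesh, cfg))
    moved = mesh.transformed(translation=(tx, ty, tz), scale=scale)
    other = normalize(sample_point_cloud(moved, cfg))
    np.testing.assert_allclose(base.points, other.points, atol=1e-6)


class TestPlyRoundTrip:
    def test_round_trip_preserves_coordinates_and_provenance(self, tmp_path, tetra_mesh):
        pc = normalize(sample_point_cloud(tetra_mesh, SamplerConfig(n_points=100, seed=6)))
        p = write_point_cloud(pc, tmp_path / "c.ply")
        back = read_point_cloud(p)
        assert np.abs(back.points - pc.points).max() < 1e-6
        assert back.provenance == pc.provenance

    def test_empty_path_raises(self, tetra_mesh):
        pc = sample_point_cloud(tetra_mesh, SamplerConfig(n_points=10, seed=0))
        with pytest.raises(PointCloudIOError):
            write_point_cloud(pc, "")

    def test_malformed_file_raises(self, tmp_path):
        p = tmp_path / "bad.ply"
        p.write_text("not a ply\n")
        with pytest.raises(PointCloudIOError):
            read_point_cloud(p)
        with pytest.raises(PointCloudIOError):
            read_point_cloud(tmp_path / "absent.ply")


class TestAgainstTrimesh:
    """Independent cross-checks against trimesh's own loader and sampler."""

    def test_obj_parser_agrees_with_trimesh_loader(self, tmp_path):
        import trimesh

        from prepscore.synthetic import PrepParams, generate_mesh, write_obj

        mesh = generate_mesh(PrepParams(seed=8, mesh_resolution=2, include_adjacent_teeth=False))
        p = write_obj(mesh, tmp_path / "x.obj")
        ours = read_obj(p)
        theirs = trimesh.load(str(p), process=False, force="mesh")
        np.testing.assert_allclose(ours.vertices, np.asarray(theirs.vertices), atol=1e-8)
        np.testing.assert_array_equal(ours.faces, np.asarray(theirs.faces))

    def test_sampler_distribution_matches_trimesh_sampler(self, two_face_mesh):
        """Both samplers put ~90% of points on the 9x-area face."""
        import trimesh

        n = 20_000
        pc = sample_point_cloud(two_face_mesh, SamplerConfig(n_points=n, seed=13))
        tm = trimesh.Trimesh(
            vertices=two_face_mesh.vertices, faces=two_face_mesh.faces, process=False
        )
        theirs, _ = trimesh.sample.sample_surface(tm, n, seed=13)
        ours_frac = np.mean(pc.points[:, 0] < 9.0)
        theirs_frac = np.mean(np.asarray(theirs)[:, 0] < 9.0)
        assert abs(ours_frac - 0.9) < 0.01
        assert abs(ours_frac - theirs_frac) < 0.02
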