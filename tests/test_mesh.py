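"""Mesh container, STL I/O, volume, smoothing and curvature estimation."""

import numpy as np
import pytest
import trimesh

from cranioshape.mesh import (CurvatureField, MeshValidationError, TriangleMesh,
                              closest_point_on_mesh, mesh_volume,
                              principal_curvatures, read_stl, taubin_smooth,
                              write_curvature_csv, write_curvature_ply, write_stl)
from conftest import make_cylinder, make_icosphere

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


class TestIO:
    def test_ascii_single_triangle(self, tmp_path):
        p = tmp_path / "tri.stl"
        p.write_text(ASCII_TRIANGLE)
        m = read_stl(p)
        assert m.n_vertices == 3 and m.n_faces == 1

    def test_binary_roundtrip_welds_vertices(self, tmp_path):
        m = make_icosphere(30.0, 3)
        p = tmp_path / "ico.stl"
        write_stl(m, p)
        m2 = read_stl(p)
        assert m2.n_vertices == m.n_vertices
        assert m2.n_faces == m.n_faces
        # same vertex set up to ordering (STL stores float32)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(m.vertices).query(m2.vertices)
        assert d.max() < 1e-3

    def test_empty_stl_rejected(self, tmp_path):
        p = tmp_path / "empty.stl"
        p.write_text("solid nothing\nendsolid nothing\n")
        with pytest.raises((MeshValidationError, IOError)):
            read_stl(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            read_stl(tmp_path / "nope.stl")

    def test_curvature_exports(self, tmp_path):
        m = make_icosphere(20.0, 2)
        f = principal_curvatures(m)
        write_curvature_csv(f, tmp_path / "c.csv")
        write_curvature_ply(m, f, tmp_path / "c.ply")
        data = np.loadtxt(tmp_path / "c.csv", delimiter=",", skiprows=1)
        assert data.shape == (m.n_vertices, 3)
        header = (tmp_path / "c.ply").read_text().splitlines()
        assert header[0] == "ply" and "property float k1" in header


class TestValidation:
    def test_degenerate_face(self):
        with pytest.raises(MeshValidationError):
            TriangleMesh(np.eye(3), np.array([[0, 0, 1]]))

    def test_out_of_range_index(self):
        with pytest.raises(MeshValidationError):
            TriangleMesh(np.eye(3), np.array([[0, 1, 5]]))

    def test_non_finite(self):
        v = np.eye(3)
        v[0, 0] = np.nan
        with pytest.raises(MeshValidationError):
            TriangleMesh(v, np.array([[0, 1, 2]]))


class TestVolume:
    def test_cube_is_one_ml(self):
        box = trimesh.creation.box(extents=(10.0, 10.0, 10.0))
        assert mesh_volume(TriangleMesh.from_trimesh(box)) == pytest.approx(1.0)

    def test_sphere_within_refinement_error(self):
        m = make_icosphere(50.0, 4)
        analytic = 4 / 3 * np.pi * 50 ** 3 / 1000
        assert mesh_volume(m) == pytest.approx(analytic, rel=0.01)

    def test_orientation_flip_gives_same_volume(self):
        m = make_icosphere(20.0, 2)
        flipped = TriangleMesh(m.vertices, m.faces[:, ::-1])
        assert mesh_volume(flipped) == pytest.approx(mesh_volume(m))

    def test_open_mesh_rejected(self):
        tri = TriangleMesh(np.eye(3), np.array([[0, 1, 2]]))
        with pytest.raises(MeshValidationError, match="boundary"):
            mesh_volume(tri)

    def test_additive_over_disjoint_components(self):
        a = make_icosphere(20.0, 2)
        b = make_icosphere(10.0, 2)
        both = TriangleMesh(np.vstack([a.vertices, b.vertices + 100.0]),
                            np.vstack([a.faces, b.faces + a.n_vertices]))
        assert mesh_volume(both) == pytest.approx(mesh_volume(a) + mesh_volume(b))


class TestTaubin:
    def test_zero_iterations_identity(self):
        m = make_icosphere(20.0, 2)
        out = taubin_smooth(m, 0)
        assert np.array_equal(out.vertices, m.vertices)

    def test_invalid_factor_pair(self):
        m = make_icosphere(20.0, 2)
        with pytest.raises(ValueError):
            taubin_smooth(m, 5, shrink_factor=0.5, inflate_factor=-0.3)
        with pytest.raises(ValueError):
            taubin_smooth(m, 5, shrink_factor=1.5, inflate_factor=-1.6)

    def test_noise_reduction_on_sphere(self):
        rng = np.random.default_rng(0)
        m = make_icosphere(50.0, 4)
        noisy = TriangleMesh(m.vertices + rng.normal(0, 0.5, m.vertices.shape), m.faces)
        smoothed = taubin_smooth(noisy, 20)

        def rms(mesh):
            return np.sqrt(np.mean((np.linalg.norm(mesh.vertices, axis=1) - 50) ** 2))

        assert rms(smoothed) < 0.5 * rms(noisy)
        assert smoothed.n_vertices == noisy.n_vertices

    def test_low_shrinkage(self):
        m = make_icosphere(50.0, 3)
        out = taubin_smooth(m, 20)
        assert abs(mesh_volume(out) - mesh_volume(m)) / mesh_volume(m) < 0.02


class TestPrincipalCurvatures:
    def test_plane_is_flat(self):
        import scipy.spatial

        g = np.mgrid[0:10, 0:10].reshape(2, -1).T.astype(float)
        tri = scipy.spatial.Delaunay(g)
        m = TriangleMesh(np.column_stack([g, np.zeros(len(g))]), tri.simplices)
        f = principal_curvatures(m)
        interior = (g[:, 0] > 1) & (g[:, 0] < 8) & (g[:, 1] > 1) & (g[:, 1] < 8)
        assert np.abs(f.k1[interior]).max() < 1e-6
        assert np.abs(f.k2[interior]).max() < 1e-6

    @pytest.mark.parametrize("radius", [20.0, 50.0, 80.0])
    def test_sphere_curvature(self, radius):
        f = principal_curvatures(make_icosphere(radius, 4))
        assert np.median(np.abs(f.k1 - 1 / radius)) * radius < 0.05
        assert np.median(np.abs(f.k2 - 1 / radius)) * radius < 0.05
        # convex-outward convention: positive on a sphere
        assert np.median(f.k1) > 0

    def test_cylinder_curvatures(self):
        m = make_cylinder(20.0)
        f = principal_curvatures(m)
        interior = np.abs(m.vertices[:, 2]) < 30
        assert np.median(f.k1[interior]) == pytest.approx(0.05, rel=0.05)
        assert np.abs(f.k2[interior]).max() < 0.005

    def test_rigid_invariance(self):
        from scipy.spatial.transform import Rotation

        m = make_icosphere(50.0, 3)
        f0 = principal_curvatures(m)
        R = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
        f1 = principal_curvatures(m.transformed(R, np.array([10.0, -5.0, 3.0])))
        assert np.abs(f1.k1 - f0.k1).max() < 1e-9 * np.abs(f0.k1).max()

    def test_scaling_covariance(self):
        m = make_icosphere(50.0, 3)
        f0 = principal_curvatures(m)
        f2 = principal_curvatures(TriangleMesh(m.vertices * 2.0, m.faces))
        assert np.allclose(f2.k1, f0.k1 / 2.0, atol=1e-10)

    def test_flip_convention(self):
        f = CurvatureField(np.array([0.05, 0.02]), np.array([0.01, -0.03]))
        g = f.flip()
        assert g.convention == "concave_positive"
        assert np.allclose(g.k1, [-0.01, 0.03]) and np.allclose(g.k2, [-0.05, -0.02])
        assert (g.k1 >= g.k2).all()

    def test_sparse_neighbourhood_fallback_warns(self):
        # a tetrahedron has 3 neighbours per vertex: every vertex falls back
        tm = trimesh.creation.icosahedron()
        m = TriangleMesh.from_trimesh(tm)
        with pytest.warns(RuntimeWarning):
            principal_curvatures(TriangleMesh(np.eye(4, 3) * 10 + 1,
                                              np.array([[0, 1, 2], [0, 3, 1],
                                                        [1, 3, 2], [2, 3, 0]])),
                                 ring=1)


def test_closest_point_on_mesh_is_on_surface():
    m = make_icosphere(30.0, 3)
    pts = np.array([[50.0, 0.0, 0.0], [0.0, 0.0, -45.0]])
    cp, d = closest_point_on_mesh(m, pts)
    assert d == pytest.approx(np.abs(np.linalg.norm(pts, axis=1) - 30), abs=0.2)
    assert np.linalg.norm(cp, axis=1) == pytest.approx(30.0, abs=0.2)
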