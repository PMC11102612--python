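"""Univariate descriptors, Frankfurt frame, TPS and semi-landmark sliding."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cranioshape.anthropometry import (ANATOMICAL_NAMES, OrbitalLandmarkSet,
                                       MeasureRecord, ThinPlateSpline3D,
                                       anatomical_frame, cephalic_index,
                                       frankfurt_plane, interfrontal_angle,
                                       interorbital_distance, orbital_ratio,
                                       slide_semilandmarks, to_frame,
                                       tps_project_semilandmarks)
from cranioshape.mesh import TriangleMesh
from cranioshape.registration import (CranialLandmarkSet,
                                      DegenerateConfigurationError, LandmarkError)
from conftest import make_icosphere


def orbit_set(anat, semis=None, rng=None):
    if semis is None:
        rng = rng or np.random.default_rng(0)
        semis = rng.normal(0, 30, (50, 3))
    return OrbitalLandmarkSet({f"LM{i + 1}": anat[i] for i in range(8)}, semis)


@pytest.fixture
def flat_landmarks():
    """Frankfurt plane z = 0; porions on x-axis; anterior = +y."""
    return CranialLandmarkSet({
        "porion_L": [-60, 0, 0], "porion_R": [60, 0, 0],
        "infraorbital_foramen_L": [-30, 70, 0], "infraorbital_foramen_R": [30, 70, 0],
        "supraorbital_notch_L": [-15, 85, 0], "supraorbital_notch_R": [15, 85, 0],
        "opisthion": [0, -80, -10], "lambda": [0, -70, 60],
    })


class TestLinearMeasures:
    def test_interorbital_distance(self):
        anat = np.zeros((8, 3))
        anat[0] = [-8, 0, 0]
        anat[1] = [8, 0, 0]
        anat[2:] = np.arange(18).reshape(6, 3)
        assert interorbital_distance(orbit_set(anat)) == pytest.approx(16.0)

    def test_coincident_medial_landmarks_warn(self):
        anat = np.arange(24, dtype=float).reshape(8, 3)
        anat[1] = anat[0]
        with pytest.warns(RuntimeWarning):
            assert interorbital_distance(orbit_set(anat)) == 0.0

    def test_orbital_ratio_arithmetic(self):
        anat = np.zeros((8, 3))
        anat[0] = [-10, 0, 0]; anat[4] = [-50, 0, 0]      # width 40 (L)
        anat[1] = [10, 0, 0]; anat[5] = [50, 0, 0]        # width 40 (R)
        anat[2] = [-30, 0, 15]; anat[6] = [-30, 0, -15]   # height 30 (L)
        anat[3] = [30, 0, 15]; anat[7] = [30, 0, -15]     # height 30 (R)
        assert orbital_ratio(orbit_set(anat)) == pytest.approx(0.75)

    def test_square_orbit_ratio_one(self):
        anat = np.zeros((8, 3))
        anat[0] = [-10, 0, 0]; anat[4] = [-40, 0, 0]
        anat[1] = [10, 0, 0]; anat[5] = [40, 0, 0]
        anat[2] = [-25, 0, 15]; anat[6] = [-25, 0, -15]
        anat[3] = [25, 0, 15]; anat[7] = [25, 0, -15]
        assert orbital_ratio(orbit_set(anat)) == pytest.approx(1.0)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(2)
        anat = rng.normal(0, 20, (8, 3))
        mirrored = anat.copy()
        mirrored[:, 0] *= -1
        # swap left/right pairs
        mirrored = mirrored[[1, 0, 3, 2, 5, 4, 7, 6]]
        assert orbital_ratio(orbit_set(mirrored)) == pytest.approx(
            orbital_ratio(orbit_set(anat)))

    def test_measure_record_validation(self):
        with pytest.raises(ValueError):
            MeasureRecord("s", "C", 100, "f", CURV=0.02, IFA=200.0, CI=0.8,
                          DIST=17, RATIO=0.9, ICV=900)
        with pytest.raises(ValueError):
            MeasureRecord("s", "C", 100, "f", CURV=0.02, IFA=120.0, CI=0.8,
                          DIST=-1, RATIO=0.9, ICV=900)


class TestFrankfurtFrame:
    def test_coplanar_construction(self, flat_landmarks):
        point, normal = frankfurt_plane(flat_landmarks)
        assert abs(point[2]) < 1e-9
        assert np.allclose(np.abs(normal), [0, 0, 1])
        assert normal[2] > 0  # oriented towards lambda

    def test_translation(self, flat_landmarks):
        moved = flat_landmarks.transformed(np.eye(3), np.array([0.0, 0.0, 10.0]))
        point, normal = frankfurt_plane(moved)
        assert point[2] == pytest.approx(10.0)

    def test_collinear_error(self):
        lms = CranialLandmarkSet({
            "porion_L": [-60, 0, 0], "porion_R": [60, 0, 0],
            "infraorbital_foramen_L": [-30, 0, 0], "infraorbital_foramen_R": [30, 0, 0],
            "supraorbital_notch_L": [-15, 85, 0], "supraorbital_notch_R": [15, 85, 0],
            "opisthion": [0, -80, -10], "lambda": [0, -70, 60]})
        with pytest.raises(DegenerateConfigurationError):
            frankfurt_plane(lms)


class TestInterfrontalAngle:
    def mesh_with_apex(self, apex):
        pts = np.array([apex, [-40.0, 0.0, 0.0], [40.0, 0.0, 0.0],
                        [0.0, -40.0, 5.0]])
        faces = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
        return TriangleMesh(pts, faces)

    def test_closed_form_right_angle(self, flat_landmarks):
        mesh = self.mesh_with_apex([0.0, 100.0, 0.0])
        # apex (0,100), notches (+-15, 85): angle = 2 atan(15/15) = 90 deg
        assert interfrontal_angle(mesh, flat_landmarks) == pytest.approx(90.0, abs=1e-9)

    def test_collinear_limit(self, flat_landmarks):
        mesh = self.mesh_with_apex([0.0, 85.0, 0.0])
        assert interfrontal_angle(mesh, flat_landmarks) == pytest.approx(180.0)

    def test_rigid_invariance(self, flat_landmarks):
        mesh = self.mesh_with_apex([3.0, 97.0, 4.0])
        a0 = interfrontal_angle(mesh, flat_landmarks)
        R = Rotation.from_euler("xyz", [11, 22, 33], degrees=True).as_matrix()
        t = np.array([4.0, -6.0, 9.0])
        a1 = interfrontal_angle(mesh.transformed(R, t),
                                flat_landmarks.transformed(R, t))
        assert a1 == pytest.approx(a0, abs=1e-9)


class TestCephalicIndex:
    def test_ellipsoid(self):
        m = make_icosphere(1.0, 3)
        ell = TriangleMesh(m.vertices * np.array([65.0, 80.0, 70.0]), m.faces)
        assert cephalic_index(ell) == pytest.approx(0.8125, abs=1e-6)

    def test_sphere(self):
        assert cephalic_index(make_icosphere(50.0, 3)) == pytest.approx(1.0, abs=1e-6)

    def test_frame_dependence_reciprocal(self):
        m = make_icosphere(1.0, 3)
        ell = TriangleMesh(m.vertices * np.array([65.0, 80.0, 70.0]), m.faces)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        rotated = ell.transformed(Rz, np.zeros(3))
        assert cephalic_index(rotated) == pytest.approx(1 / cephalic_index(ell), rel=1e-6)


class TestTPS:
    def test_identity_warp(self):
        rng = np.random.default_rng(0)
        anat = rng.normal(0, 30, (8, 3))
        ols = orbit_set(anat, rng.normal(0, 30, (50, 3)))
        out = tps_project_semilandmarks(ols, anat, anat, None)
        assert np.abs(out.semilandmarks - ols.semilandmarks).max() < 1e-6

    def test_uniform_scaling_special_case(self):
        rng = np.random.default_rng(1)
        anat = rng.normal(0, 30, (8, 3))
        ols = orbit_set(anat, rng.normal(0, 30, (50, 3)))
        out = tps_project_semilandmarks(ols, anat, anat * 1.1, None)
        assert np.abs(out.semilandmarks - 1.1 * ols.semilandmarks).max() < 1e-6

    def test_control_points_reproduced(self):
        rng = np.random.default_rng(2)
        src = rng.normal(0, 30, (8, 3))
        dst = src + rng.normal(0, 5, (8, 3))
        tps = ThinPlateSpline3D(src, dst)
        assert np.abs(tps.transform(src) - dst).max() < 1e-6

    def test_snapped_points_on_surface(self):
        rng = np.random.default_rng(3)
        mesh = make_icosphere(40.0, 3)
        anat = rng.normal(0, 20, (8, 3)) + np.array([0, 35, 0])
        ols = orbit_set(anat, rng.normal(0, 5, (50, 3)) + np.array([0, 38, 0]))
        out = tps_project_semilandmarks(ols, anat, anat, mesh)
        from cranioshape.mesh import closest_point_on_mesh
        _, d = closest_point_on_mesh(mesh, out.semilandmarks)
        assert d.max() < 1e-9

    def test_coplanar_controls_rejected(self):
        src = np.zeros((8, 3))
        src[:, :2] = np.random.default_rng(4).normal(0, 10, (8, 2))
        with pytest.raises(DegenerateConfigurationError):
            ThinPlateSpline3D(src, src)


class TestSliding:
    def make_subjects(self, n, noise, rng):
        anat = rng.normal(0, 30, (8, 3))
        semis = rng.normal(0, 30, (50, 3))
        return ([orbit_set(anat, semis + rng.normal(0, noise, semis.shape))
                 for _ in range(n)],
                orbit_set(anat, semis))

    def test_reference_is_fixed_point(self):
        rng = np.random.default_rng(5)
        subs, ref = self.make_subjects(3, 0.0, rng)
        slid, _ = slide_semilandmarks(subs, reference=ref.full_configuration(),
                                      iterations=2)
        for orig, new in zip(subs, slid):
            assert np.abs(new.semilandmarks - orig.semilandmarks).max() < 1e-8

    def test_energy_non_increasing(self):
        rng = np.random.default_rng(6)
        subs, ref = self.make_subjects(5, 1.0, rng)
        _, info = slide_semilandmarks(subs, iterations=4)
        e = info["energy"]
        assert len(e) >= 1 and all(v >= 0 for v in e)
        assert all(b <= a + 1e-9 for a, b in zip(e, e[1:]))

    def test_anatomical_landmarks_immobile(self):
        rng = np.random.default_rng(7)
        subs, ref = self.make_subjects(4, 1.0, rng)
        slid, _ = slide_semilandmarks(subs, iterations=3)
        for orig, new in zip(subs, slid):
            assert np.array_equal(new.as_array(), orig.as_array())


class TestLandmarkSetValidation:
    def test_wrong_semilandmark_count(self):
        anat = np.arange(24, dtype=float).reshape(8, 3)
        with pytest.raises(LandmarkError):
            OrbitalLandmarkSet({f"LM{i + 1}": anat[i] for i in range(8)},
                               np.zeros((40, 3)))

    def test_missing_anatomical(self):
        with pytest.raises(LandmarkError):
            OrbitalLandmarkSet({"LM1": [0, 0, 0]}, np.zeros((50, 3)))


def test_measures_rigid_invariance_randomised():
    """DIST/RATIO invariant under arbitrary rigid motions of the landmarks."""
    rng = np.random.default_rng(8)
    anat = rng.normal(0, 25, (8, 3))
    base = orbit_set(anat, rng.normal(0, 25, (50, 3)))
    d0, r0 = interorbital_distance(base), orbital_ratio(base)
    for i in range(5):
        R = Rotation.random(random_state=i).as_matrix()
        t = rng.normal(0, 100, 3)
        moved = OrbitalLandmarkSet({k: R @ v + t for k, v in base.anatomical.items()},
                                   base.semilandmarks @ R.T + t)
        assert interorbital_distance(moved) == pytest.approx(d0)
        assert orbital_ratio(moved) == pytest.approx(r0)
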