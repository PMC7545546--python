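"""Landmark geometry, pose estimation, and standardized anteversion."""

import numpy as np
import pytest

from cupversion import (
    InconsistentLandmarksError,
    MissingLandmarkError,
    NoPoseSolutionError,
    PelvicLandmarks,
    PelvicPose,
    PlanarMeasurement,
    StandardizationConfig,
    displacements,
    estimate_pelvic_pose,
    pelvic_axis,
    standardized_anteversion,
    trans_teardrop_line,
)
from cupversion.landmarks import pose_matrix, rot_craniocaudal, rot_transverse


def _lm(symphysis, scj, td_l=(316.0, 256.0), td_r=(196.0, 256.0)):
    return PelvicLandmarks(symphysis=symphysis, scj=scj, teardrop_l=td_l, teardrop_r=td_r)


class TestPelvicAxis:
    def test_direction_scj_to_symphysis(self):
        lm = _lm(symphysis=(0.0, 10.0), scj=(0.0, 0.0))
        np.testing.assert_allclose(pelvic_axis(lm), [0.0, 1.0])

    def test_normalization(self):
        lm = _lm(symphysis=(3.0, 4.0), scj=(0.0, 0.0))
        np.testing.assert_allclose(pelvic_axis(lm), [0.6, 0.8])

    def test_coincident_points(self):
        lm = _lm(symphysis=(3.0, 4.0), scj=(3.0, 4.0))
        with pytest.raises(InconsistentLandmarksError):
            pelvic_axis(lm)


class TestTransTeardropLine:
    def test_horizontal_line(self):
        lm = _lm((0, 30), (0, 0), td_l=(50.0, 0.0), td_r=(-50.0, 0.0))
        _, d = trans_teardrop_line(lm)
        assert abs(d[1] / d[0]) < 1e-12

    def test_sloped_line(self):
        lm = _lm((0, 30), (0, 0), td_l=(50.0, 10.0), td_r=(-50.0, 0.0))
        _, d = trans_teardrop_line(lm)
        assert d[1] / d[0] == pytest.approx(0.1)

    def test_coincident_teardrops_rejected_at_construction(self):
        with pytest.raises(InconsistentLandmarksError):
            _lm((0, 30), (0, 0), td_l=(5.0, 5.0), td_r=(5.0, 5.0))


class TestMissingLandmarks:
    def test_missing_teardrop_named(self):
        with pytest.raises(MissingLandmarkError, match="teardrop_r"):
            PelvicLandmarks(symphysis=(0, 0), scj=(0, 1),
                            teardrop_l=(1, 0), teardrop_r=None)

    def test_nan_landmark_named(self):
        with pytest.raises(MissingLandmarkError, match="scj"):
            _lm(symphysis=(0.0, 0.0), scj=(float("nan"), 1.0))


class TestDisplacements:
    def test_scj_superior_gives_positive_v(self):
        # image y grows downward: superior SCJ has smaller y
        lm = _lm(symphysis=(256.0, 276.0), scj=(256.0, 256.0))
        h, v = displacements(lm, "right")
        assert h == pytest.approx(0.0, abs=1e-12)
        assert v == pytest.approx(20.0)

    def test_h_positive_toward_measured_acetabulum(self):
        # teardrop_l at larger image x: displacement toward the left hip
        lm = _lm(symphysis=(256.0, 276.0), scj=(271.0, 276.0))
        h_left, v_left = displacements(lm, "left")
        h_right, v_right = displacements(lm, "right")
        assert h_left == pytest.approx(15.0)
        assert h_right == pytest.approx(-15.0)
        assert v_left == v_right == pytest.approx(0.0, abs=1e-12)

    def test_side_flip_changes_only_h(self):
        lm = _lm(symphysis=(250.0, 280.0), scj=(262.0, 251.0))
        hl, vl = displacements(lm, "left")
        hr, vr = displacements(lm, "right")
        assert hl == pytest.approx(-hr)
        assert vl == pytest.approx(vr)

    def test_pixel_spacing_scales_lengths(self):
        lm = _lm(symphysis=(256.0, 276.0), scj=(256.0, 256.0))
        _, v = displacements(lm, "right", pixel_spacing=0.2)
        assert v == pytest.approx(4.0)


class TestEstimatePelvicPose:
    def test_neutral_film(self):
        pose = estimate_pelvic_pose(h=0.0, v=30.0, ssd=100.0, neutral_v=30.0)
        assert pose.theta == pytest.approx(0.0, abs=1e-9)
        assert pose.phi == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [-15.0, -5.0, 0.0, 5.0, 10.0, 15.0])
    @pytest.mark.parametrize("phi", [-10.0, 0.0, 5.0, 10.0])
    def test_round_trip_against_forward_rotation(self, theta, phi):
        """Projecting the SP-SCJ segment forward then inverting recovers the pose."""
        ssd, nv = 100.0, 30.0
        depth = np.sqrt(ssd**2 - nv**2)
        s = pose_matrix(PelvicPose(theta, phi)) @ np.array([0.0, nv, -depth])
        pose = estimate_pelvic_pose(h=s[0], v=s[1], ssd=ssd, neutral_v=nv)
        assert pose.theta == pytest.approx(theta, abs=1e-6)
        assert pose.phi == pytest.approx(phi, abs=1e-6)

    def test_inconsistent_displacements(self):
        with pytest.raises(InconsistentLandmarksError):
            estimate_pelvic_pose(h=80.0, v=80.0, ssd=100.0, neutral_v=30.0)

    def test_boundary_v_equals_ssd(self):
        # SP-SCJ segment fully in the film plane: extreme but solvable tilt
        pose = estimate_pelvic_pose(h=0.0, v=100.0, ssd=100.0, neutral_v=30.0)
        assert pose.theta == pytest.approx(90.0 - np.degrees(np.arcsin(0.3)))
        assert pose.phi == 0.0

    def test_alternate_branch_differs(self):
        ssd, nv = 100.0, 30.0
        depth = np.sqrt(ssd**2 - nv**2)
        s = pose_matrix(PelvicPose(10.0, 0.0)) @ np.array([0.0, nv, -depth])
        with pytest.raises(NoPoseSolutionError):
            # the alternate tilt solution lies outside (-90, 90) here
            estimate_pelvic_pose(s[0], s[1], ssd, nv, tilt_branch="alternate")


class TestStandardizedAnteversion:
    def test_identity_pose_returns_u_exactly(self):
        pm = PlanarMeasurement(u=25.0, w=45.0, h=0.0, v=30.0, ssd=100.0, side="right")
        out = standardized_anteversion(pm, PelvicPose(0.0, 0.0))
        assert out == pytest.approx(25.0, abs=1e-9)

    def test_continuity_under_small_pose_perturbation(self):
        pm = PlanarMeasurement(u=25.0, w=45.0, h=0.0, v=30.0, ssd=100.0, side="right")
        base = standardized_anteversion(pm, PelvicPose(8.0, 4.0))
        for dth, dph in [(0.1, 0.0), (0.0, 0.1), (-0.1, 0.1)]:
            near = standardized_anteversion(pm, PelvicPose(8.0 + dth, 4.0 + dph))
            assert abs(near - base) < 1.0

    def test_rotation_matrices_orthonormal(self):
        for mat in (rot_transverse(33.0), rot_craniocaudal(-21.0)):
            np.testing.assert_allclose(mat @ mat.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(mat) == pytest.approx(1.0)


class TestMeasureFilm:
    def test_identity_pose_standardized_equals_radiographic(self, measure_synthetic):
        rec, _ = measure_synthetic(anteversion=25.0, inclination=45.0)
        assert rec.standardized_anteversion == pytest.approx(
            rec.radiographic_anteversion, abs=1e-6
        )

    def test_tilted_film_recovers_truth(self, measure_synthetic):
        rec, _ = measure_synthetic(anteversion=15.0, inclination=45.0, theta=10.0)
        assert rec.radiographic_anteversion != pytest.approx(15.0, abs=0.5)
        assert rec.standardized_anteversion == pytest.approx(15.0, abs=0.1)

    def test_tilt_sweep_standardized_constant(self, measure_synthetic):
        outs, planars = [], []
        for theta in np.arange(-15.0, 15.1, 5.0):
            rec, _ = measure_synthetic(anteversion=20.0, inclination=50.0, theta=theta)
            outs.append(rec.standardized_anteversion)
            planars.append(rec.radiographic_anteversion)
        assert np.ptp(outs) < 0.1
        assert np.ptp(planars) > 2.0

    def test_both_sides_recover_truth(self, measure_synthetic):
        for side in ("left", "right"):
            rec, _ = measure_synthetic(
                anteversion=32.0, inclination=40.0, theta=-8.0, phi=6.0, side=side
            )
            assert rec.standardized_anteversion == pytest.approx(32.0, abs=0.1)

    def test_record_carries_intermediates(self, measure_synthetic):
        rec, film = measure_synthetic(anteversion=15.0, inclination=45.0,
                                      theta=10.0, phi=5.0)
        assert rec.pose.theta == pytest.approx(10.0, abs=1e-4)
        assert rec.pose.phi == pytest.approx(5.0, abs=1e-4)
        assert rec.ssd == 100.0
        assert 0.0 <= rec.inclination <= 90.0


def test_planar_measurement_invariant():
    with pytest.raises(InconsistentLandmarksError):
        PlanarMeasurement(u=10.0, w=40.0, h=90.0, v=90.0, ssd=100.0, side="left")


def test_config_validation():
    with pytest.raises(ValueError):
        StandardizationConfig(ssd=-5.0)
    with pytest.raises(ValueError):
        StandardizationConfig(neutral_v=200.0)
    with pytest.raises(ValueError):
        StandardizationConfig(tilt_branch="bogus")
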