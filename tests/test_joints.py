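"""Pelvis frame, Harrington hip regression, midpoint centers, static run."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitpipe.joints import (JointCenterError, StaticPose, harrington_hjc,
                             harrington_local_offsets, mean_pose,
                             midpoint_center, pelvis_frame)


def _pose(extra=None):
    base = {
        "LASI": np.array([-120.0, 0.0, 0.0]),
        "RASI": np.array([120.0, 0.0, 0.0]),
        "LPSI": np.array([-60.0, -150.0, 10.0]),
        "RPSI": np.array([60.0, -150.0, 10.0]),
    }
    base.update(extra or {})
    return StaticPose(positions=base)


class TestPelvisFrame:
    def test_hand_constructed_geometry(self):
        origin, axes = pelvis_frame(np.array([-120.0, 0, 0]), np.array([120.0, 0, 0]),
                                    np.array([-60.0, -150, 0]), np.array([60.0, -150, 0]))
        np.testing.assert_allclose(origin, [0, 0, 0])
        np.testing.assert_allclose(axes[:, 2], [1, 0, 0])     # z toward RASIS
        np.testing.assert_allclose(axes[:, 0], [0, 1, 0])     # x anterior
        np.testing.assert_allclose(axes[:, 1], [0, 0, 1])     # y = z cross x

    def test_symmetric_input_origin_midway(self):
        origin, _ = pelvis_frame([0, 0, 0], [100, 0, 0], [20, -120, 0], [80, -120, 0])
        np.testing.assert_allclose(origin, [50, 0, 0])

    def test_axes_right_handed_for_random_landmarks(self, rng):
        for _ in range(20):
            pts = rng.normal(scale=100, size=(4, 3)) + [[0, 0, 0], [250, 0, 0],
                                                        [40, -150, 20], [210, -150, 20]]
            _, axes = pelvis_frame(*pts)
            np.testing.assert_allclose(axes.T @ axes, np.eye(3), atol=1e-12)
            assert np.linalg.det(axes) == pytest.approx(1.0)

    def test_collinear_landmarks_rejected(self):
        with pytest.raises(JointCenterError, match="collinear"):
            pelvis_frame([0, 0, 0], [100, 0, 0], [50, 0, 0], [60, 0, 0])


class TestHarrington:
    def test_local_offsets_hand_evaluated(self):
        """PW=240, PD=120 mm: (-0.24*120-9.9, -0.30*240-10.9, 0.33*240+7.3)."""
        np.testing.assert_allclose(harrington_local_offsets(240.0, 120.0, "right"),
                                   [-38.7, -82.9, 86.5])
        np.testing.assert_allclose(harrington_local_offsets(240.0, 120.0, "left"),
                                   [-38.7, -82.9, -86.5])

    def test_left_right_differ_only_in_z_sign(self):
        pose = _pose()
        right = harrington_hjc(pose, "right").position
        left = harrington_hjc(pose, "left").position
        # pelvis z axis is the lab x axis for this pose
        np.testing.assert_allclose(right[1:], left[1:], atol=1e-12)
        np.testing.assert_allclose(right[0], -left[0], atol=1e-12)

    def test_equivariance_under_rigid_transform(self, rng):
        """HJC commutes with any rigid motion of the pose, to 1e-9 mm."""
        pose = _pose()
        R = Rotation.random(random_state=7).as_matrix()
        t = rng.normal(scale=500, size=3)
        moved = StaticPose({k: R @ v + t for k, v in pose.positions.items()})
        for side in ("left", "right"):
            orig = harrington_hjc(pose, side).position
            new = harrington_hjc(moved, side).position
            np.testing.assert_allclose(new, R @ orig + t, atol=1e-9)

    def test_missing_landmark_named(self):
        pose = _pose()
        del pose.positions["RPSI"]
        with pytest.raises(JointCenterError, match="RPSI"):
            harrington_hjc(pose, "right")


class TestMidpoint:
    def test_exact_midpoint(self):
        pose = StaticPose({"A": np.zeros(3), "B": np.array([2.0, 4.0, 6.0])})
        np.testing.assert_array_equal(
            midpoint_center(pose, "kjc", "A", "B").position, [1.0, 2.0, 3.0])

    def test_symmetric_in_arguments_and_fixed_point(self):
        pose = StaticPose({"A": np.array([5.0, 5, 5]), "B": np.array([1.0, 0, 2])})
        ab = midpoint_center(pose, "j", "A", "B").position
        ba = midpoint_center(pose, "j", "B", "A").position
        np.testing.assert_array_equal(ab, ba)
        same = StaticPose({"A": np.ones(3), "B": np.ones(3)})
        np.testing.assert_array_equal(
            midpoint_center(same, "j", "A", "B").position, np.ones(3))

    def test_generator_truth_geometry(self, zero_noise_session):
        """Knee/ankle midpoints equal the generator's stored joint centers."""
        params, truth, acqs = zero_noise_session
        pose = mean_pose(acqs["static"])
        for label, (a, b) in {"KJC_R": ("RLEP", "RMEP"), "KJC_L": ("LLEP", "LMEP"),
                              "AJC_R": ("RLMA", "RMMA"), "AJC_L": ("LLMA", "LMMA")}.items():
            got = midpoint_center(pose, label.lower(), a, b).position
            np.testing.assert_allclose(got, truth.joint_centers[label], atol=1e-9)


class TestMeanPose:
    def test_mean_over_valid_frames_only(self, zero_noise_session):
        """The occluded RASI frames do not bias the static mean."""
        params, truth, acqs = zero_noise_session
        acq = acqs["static"]
        label, start, length = truth.static_occlusion
        traj = acq.marker(label)
        assert traj.mask[start:start + length].all()
        pose = mean_pose(acq)
        manual = traj.positions[~traj.mask].mean(axis=0)
        np.testing.assert_allclose(pose[label], manual)

    def test_too_few_valid_frames_rejected(self):
        from gaitpipe.acquisition import AcquisitionData, EventList, MarkerTrajectory
        mask = np.ones(20, dtype=bool)
        mask[:5] = False
        acq = AcquisitionData(
            markers=[MarkerTrajectory("M", np.ones((20, 3)), mask)],
            analog=[], plates=[], events=EventList([]), video_rate=100.0)
        with pytest.raises(JointCenterError, match="at least 10"):
            mean_pose(acq)


def test_static_elaboration_appends_virtual_markers(written_session):
    """The static .trc carries the original landmarks plus HJC/KJC/AJC columns."""
    from gaitpipe.runner import run_static_elaboration
    from gaitpipe.writers import read_trc
    params, truth, acqs, session_dir = written_session
    out = run_static_elaboration(session_dir, session_dir / "acquisition.xml",
                                 session_dir / "static.xml")
    markers, rate, units = read_trc(out / "static.trc")
    for virtual in ("HJC_L", "HJC_R", "KJC_L", "KJC_R", "AJC_L", "AJC_R"):
        assert virtual in markers
        # virtual markers are constant trajectories
        assert np.ptp(markers[virtual], axis=0).max() == 0.0
    assert set(truth.static_markers) <= set(markers)
    assert rate == params.video_rate
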