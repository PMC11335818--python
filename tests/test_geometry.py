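import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headgaze import geometry as geo

CEIL = geo.CameraModel(1152, 986, 1000.0, (576.0, 493.0))
BIG_MARKER_CAM = geo.CameraModel(1152, 986, 3333.0, (576.0, 493.0))
MARKER = geo.MarkerModel(0.1)


def pose(yaw=0.0, pitch=0.0, roll=0.0, t=(0.0, 0.0, 1.0)):
    return geo.PoseEstimate(geo.euler_zyx_to_matrix(yaw, pitch, roll), np.asarray(t))


# --------------------------------------------------------------------------
# projection

def test_project_centered_square():
    # 0.1 m side at 1 m with f = 1000 px -> 100 px square on the principal point
    obs = geo.project_marker(pose(), MARKER, CEIL)
    assert obs.valid
    expected = np.array([[526., 443.], [626., 443.], [626., 543.], [526., 543.]])
    np.testing.assert_allclose(obs.corners, expected, atol=1e-12)


def test_project_inplane_rotation_rotates_image():
    obs0 = geo.project_marker(pose(), MARKER, CEIL)
    obs30 = geo.project_marker(pose(yaw=30.0), MARKER, CEIL)
    th = math.radians(30.0)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    pp = np.array(CEIL.principal_point)
    rotated = (obs0.corners - pp) @ R.T + pp
    np.testing.assert_allclose(obs30.corners, rotated, atol=1e-9)


def _oracle_project(R, t, marker, cam):
    # independent transform-then-divide implementation
    out = []
    for corner in marker.corners_object():
        p = R @ corner + t
        out.append([cam.principal_point[0] + cam.focal_length * p[0] / p[2],
                    cam.principal_point[1] + cam.focal_length * p[1] / p[2]])
    return np.array(out)


def test_project_matches_transform_divide_oracle():
    p = pose(yaw=25.0, pitch=10.0, roll=5.0, t=(0.1, -0.05, 1.2))
    obs = geo.project_marker(p, MARKER, CEIL)
    oracle = _oracle_project(p.rotation, p.translation, MARKER, CEIL)
    np.testing.assert_allclose(obs.corners, oracle, atol=1e-9)


def test_project_behind_camera_invalid():
    obs = geo.project_marker(pose(t=(0, 0, -1.0)), MARKER, CEIL)
    assert not obs.valid
    assert "behind" in obs.message


# --------------------------------------------------------------------------
# planar pose recovery

def test_pose_roundtrip_identity():
    obs = geo.project_marker(pose(), MARKER, CEIL)
    est = geo.estimate_planar_pose(obs, MARKER, CEIL)
    assert abs(est.euler.yaw) < 1e-6
    np.testing.assert_allclose(est.translation, [0, 0, 1.0], atol=1e-6)


def test_pose_roundtrip_yaw_translation():
    p = pose(yaw=37.5, t=(0.05, 0.02, 1.1))
    obs = geo.project_marker(p, MARKER, CEIL)
    est = geo.estimate_planar_pose(obs, MARKER, CEIL)
    assert est.euler.yaw == pytest.approx(37.5, abs=1e-6)
    np.testing.assert_allclose(est.translation, p.translation, atol=1e-6)


def test_pose_roundtrip_100_random_poses():
    rng = np.random.default_rng(42)
    for _ in range(100):
        yaw = rng.uniform(-179, 179)
        pitch = rng.uniform(-40, 40)
        roll = rng.uniform(-40, 40)
        t = np.array([rng.uniform(-0.2, 0.2), rng.uniform(-0.2, 0.2),
                      rng.uniform(0.7, 2.0)])
        p = pose(yaw, pitch, roll, t)
        obs = geo.project_marker(p, MARKER, CEIL)
        est = geo.estimate_planar_pose(obs, MARKER, CEIL)
        np.testing.assert_allclose(est.rotation, p.rotation, atol=1e-6)
        np.testing.assert_allclose(est.translation, t, atol=1e-6)


def test_pose_rotation_always_orthonormal():
    rng = np.random.default_rng(3)
    corners = []
    for _ in range(50):
        p = pose(rng.uniform(-170, 170), rng.uniform(-30, 30),
                 rng.uniform(-30, 30), (0.02, -0.01, 1.0))
        corners.append(geo.project_marker(p, MARKER, CEIL).corners)
    R, t, low = geo.estimate_planar_pose_batch(np.array(corners), MARKER, CEIL)
    np.testing.assert_allclose(R @ np.swapaxes(R, 1, 2),
                               np.tile(np.eye(3), (len(R), 1, 1)), atol=1e-9)
    assert np.all(np.linalg.det(R) > 0)
    assert np.all(t[:, 2] > 0)


def test_yaw_invariant_to_marker_distance():
    for k in (0.5, 1.0, 2.0, 3.5):
        p = pose(yaw=23.0, t=(0.0, 0.0, 1.0 * k))
        obs = geo.project_marker(p, MARKER, CEIL)
        est = geo.estimate_planar_pose(obs, MARKER, CEIL)
        assert est.euler.yaw == pytest.approx(23.0, abs=1e-6)


def test_inplane_rotation_equivariance():
    obs = geo.project_marker(pose(yaw=10.0), MARKER, CEIL)
    th = math.radians(25.0)
    R2 = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    pp = np.array(CEIL.principal_point)
    rotated = geo.MarkerObservation(0.0, (obs.corners - pp) @ R2.T + pp)
    est0 = geo.estimate_planar_pose(obs, MARKER, CEIL)
    est1 = geo.estimate_planar_pose(rotated, MARKER, CEIL)
    assert est1.euler.yaw - est0.euler.yaw == pytest.approx(25.0, abs=1e-6)


def test_pose_noise_monte_carlo_yaw_error():
    # 0.5 px corner noise on a marker imaging to > 80,000 px^2: yaw stays
    # accurate to < 0.1 deg RMS over 1000 seeded trials
    rng = np.random.default_rng(7)
    p = pose(yaw=15.0, t=(0.0, 0.0, 1.0))
    obs = geo.project_marker(p, MARKER, BIG_MARKER_CAM)
    side = np.linalg.norm(obs.corners[1] - obs.corners[0])
    assert side ** 2 > 80_000
    noisy = obs.corners[None] + rng.normal(0.0, 0.5, (1000, 4, 2))
    R, _, _ = geo.estimate_planar_pose_batch(noisy, MARKER, BIG_MARKER_CAM)
    yaws = np.degrees(np.arctan2(R[:, 1, 0], R[:, 0, 0]))
    err = yaws - 15.0
    assert np.sqrt(np.mean(err ** 2)) < 0.1
    assert abs(err).max() < 0.5


def test_collinear_corners_rejected():
    bad = geo.MarkerObservation(0.0, [[0, 0], [1, 1], [2, 2], [3, 3]])
    with pytest.raises(ValueError, match="collinear"):
        geo.estimate_planar_pose(bad, MARKER, CEIL)


# --------------------------------------------------------------------------
# head yaw

def test_pose_to_head_yaw_reference():
    assert geo.pose_to_head_yaw(pose(yaw=40.0), reference_yaw=40.0) == pytest.approx(0.0)
    assert geo.pose_to_head_yaw(pose(yaw=110.0), reference_yaw=40.0) == pytest.approx(70.0)


def test_pose_to_head_yaw_wraps():
    assert geo.pose_to_head_yaw(pose(yaw=-170.0), reference_yaw=170.0) == pytest.approx(20.0)


def test_head_yaw_trace_noise_free():
    # simulated 90-degree head turn rendered to corners and recovered
    yaws = np.linspace(0.0, 90.0, 181)
    ref = 20.0
    R = np.array([geo.euler_zyx_to_matrix(ref + y, 0, 0) for y in yaws])
    t = np.tile([0.0, 0.0, 1.0], (len(yaws), 1))
    corners = geo.project_marker_batch(R, t, MARKER, BIG_MARKER_CAM)
    for y_true, c in zip(yaws, corners):
        est = geo.estimate_planar_pose(geo.MarkerObservation(0.0, c),
                                       MARKER, BIG_MARKER_CAM)
        assert geo.pose_to_head_yaw(est, ref) == pytest.approx(y_true, abs=1e-6)


def test_gimbal_lock_raises():
    with pytest.raises(ValueError, match="gimbal"):
        geo.matrix_to_euler_zyx(geo.euler_zyx_to_matrix(10.0, 89.9, 0.0))


# --------------------------------------------------------------------------
# rotation representations

def test_rotvec_zero_is_identity():
    np.testing.assert_allclose(geo.rotvec_to_matrix([0, 0, 0]), np.eye(3))


def test_rotvec_quarter_turn_about_z():
    R = geo.rotvec_to_matrix([0, 0, math.pi / 2])
    np.testing.assert_allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)


def test_rotvec_roundtrip_200_random():
    rng = np.random.default_rng(0)
    for _ in range(200):
        v = rng.normal(size=3)
        v = v / np.linalg.norm(v) * rng.uniform(1e-3, math.pi - 1e-3)
        np.testing.assert_allclose(
            geo.matrix_to_rotvec(geo.rotvec_to_matrix(v)), v, atol=1e-10)


def test_rotvec_matches_scipy():
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(1)
    for _ in range(50):
        v = rng.normal(size=3)
        np.testing.assert_allclose(geo.rotvec_to_matrix(v),
                                   Rotation.from_rotvec(v).as_matrix(),
                                   atol=1e-12)


@given(yaw=st.floats(-179.0, 179.0), pitch=st.floats(-80.0, 80.0),
       roll=st.floats(-179.0, 179.0))
@settings(max_examples=100, deadline=None)
def test_euler_roundtrip(yaw, pitch, roll):
    e = geo.matrix_to_euler_zyx(geo.euler_zyx_to_matrix(yaw, pitch, roll))
    assert e.yaw == pytest.approx(yaw, abs=1e-8)
    assert e.pitch == pytest.approx(pitch, abs=1e-8)
    assert e.roll == pytest.approx(roll, abs=1e-8)


# --------------------------------------------------------------------------
# analytic setup helpers and camera model

def test_angular_subtense_values():
    assert round(geo.angular_subtense(0.008, 3.43), 2) == 0.13
    assert round(geo.angular_subtense(0.008, 2.5), 2) == 0.18


def test_offset_angle_values():
    assert round(geo.offset_angle(0.05, 2.45), 1) == 1.2
    assert round(geo.offset_angle(0.07, 2.45), 1) == 1.6


def test_camera_fov_focal_consistency():
    cam = geo.CameraModel.from_fov(1088, 1080, 82.0)
    assert cam.fov_horizontal == pytest.approx(82.0, abs=1e-9)
    assert cam.focal_length == pytest.approx((1088 / 2) / math.tan(math.radians(41.0)))


def test_camera_json_roundtrip(tmp_path):
    cam = geo.CameraModel.from_fov(1088, 1080, 82.0)
    f = tmp_path / "cam.json"
    cam.to_json(f)
    assert geo.CameraModel.from_json(f) == cam
    assert set(json.loads(f.read_text())) == {"width", "height",
                                              "focal_length_px",
                                              "principal_point"}


def test_camera_validation():
    with pytest.raises(ValueError):
        geo.CameraModel(100, 100, -5.0, (50, 50))
    with pytest.raises(ValueError):
        geo.CameraModel(100, 100, 100.0, (500, 50))
    with pytest.raises(ValueError):
        geo.MarkerModel(0.0)


def test_wrap_degrees():
    assert geo.wrap_degrees(180.0) == 180.0
    assert geo.wrap_degrees(-180.0) == 180.0
    assert geo.wrap_degrees(540.0) == 180.0
    np.testing.assert_allclose(geo.wrap_degrees(np.array([350.0, -190.0])),
                               [-10.0, 170.0])
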