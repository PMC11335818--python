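"""Pinhole-camera geometry and planar fiducial-marker pose estimation.

The head-orientation signal is obtained by observing a square planar marker,
worn on the head, with a fixed downward-looking camera.  Pose is recovered
from the four marker corners by a direct-linear-transform homography
normalized with the camera intrinsics and decomposed into rotation +
translation.  Head yaw is the rotation about the camera's optical axis
(which coincides with the vertical when the camera looks straight down).

All image coordinates are in pixels with x rightward and y downward; the
camera frame has z along the optical axis pointing away from the camera.
Angles are degrees throughout the public API.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CameraModel",
    "MarkerModel",
    "MarkerObservation",
    "PoseEstimate",
    "EulerAngles",
    "project_marker",
    "project_marker_batch",
    "estimate_planar_pose",
    "estimate_planar_pose_batch",
    "pose_to_head_yaw",
    "rotvec_to_matrix",
    "matrix_to_rotvec",
    "euler_zyx_to_matrix",
    "matrix_to_euler_zyx",
    "wrap_degrees",
    "angular_subtense",
    "offset_angle",
]


# --------------------------------------------------------------------------
# small analytic helpers (setup design checks)

def angular_subtense(diameter_m: float, distance_m: float) -> float:
    """Angular diameter in degrees of a circular object seen face-on.

    ``2 * atan(d / 2D)`` — exact, not the small-angle approximation.
    """
    if distance_m <= 0:
        raise ValueError("distance must be positive")
    return math.degrees(2.0 * math.atan2(diameter_m / 2.0, distance_m))


def offset_angle(offset_m: float, distance_m: float) -> float:
    """Angle in degrees subtended by a lateral/vertical offset at a distance.

    Used to budget gaze-angle errors from head translation or target-height
    mismatch: ``atan(offset / distance)``.
    """
    if distance_m <= 0:
        raise ValueError("distance must be positive")
    return math.degrees(math.atan2(offset_m, distance_m))


def wrap_degrees(angle):
    """Wrap angle(s) to the half-open interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return float(wrapped) if np.isscalar(angle) or wrapped.ndim == 0 else wrapped


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole camera with square pixels and no distortion.

    ``focal_length`` is in pixels.  If corner/gaze input was captured through
    a lens with noticeable distortion it must be undistorted upstream; this
    model deliberately has no distortion terms.
    """

    image_width: int
    image_height: int
    focal_length: float
    principal_point: tuple[float, float]

    def __post_init__(self):
        if self.focal_length <= 0:
            raise ValueError("focal_length must be positive")
        px, py = self.principal_point
        if not (0 <= px <= self.image_width and 0 <= py <= self.image_height):
            raise ValueError("principal_point outside image bounds")

    @property
    def fov_horizontal(self) -> float:
        """Horizontal field of view in degrees, f = (W/2)/tan(fov/2)."""
        return math.degrees(2.0 * math.atan2(self.image_width / 2.0, self.focal_length))

    @classmethod
    def from_fov(cls, image_width: int, image_height: int, fov_horizontal_deg: float,
                 principal_point: tuple[float, float] | None = None) -> "CameraModel":
        f = (image_width / 2.0) / math.tan(math.radians(fov_horizontal_deg) / 2.0)
        if principal_point is None:
            principal_point = (image_width / 2.0, image_height / 2.0)
        return cls(image_width, image_height, f, principal_point)

    def to_dict(self) -> dict:
        return {
            "width": self.image_width,
            "height": self.image_height,
            "focal_length_px": self.focal_length,
            "principal_point": list(self.principal_point),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(int(d["width"]), int(d["height"]), float(d["focal_length_px"]),
                   (float(d["principal_point"][0]), float(d["principal_point"][1])))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class MarkerModel:
    """Square planar marker; corners at z=0 in the marker's own frame.

    Corner order is fixed: top-left, top-right, bottom-right, bottom-left
    (marker frame x rightward, y downward, matching image axes for an
    identity pose).
    """

    side_length: float

    def __post_init__(self):
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")

    def corners_object(self) -> np.ndarray:
        """(4, 3) corner coordinates in meters, marker frame, z = 0."""
        h = self.side_length / 2.0
        return np.array([
            [-h, -h, 0.0],
            [h, -h, 0.0],
            [h, h, 0.0],
            [-h, h, 0.0],
        ])


@dataclass
class MarkerObservation:
    timestamp: float
    corners: np.ndarray  # (4, 2) pixels
    valid: bool = True
    message: str = ""

    def __post_init__(self):
        self.corners = np.asarray(self.corners, dtype=float).reshape(4, 2)


@dataclass
class PoseEstimate:
    """Rigid transform taking marker-frame points into the camera frame."""

    rotation: np.ndarray        # (3, 3) orthonormal, det +1
    translation: np.ndarray     # (3,) meters, camera frame
    low_confidence: bool = False

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        _assert_rotation(self.rotation)

    @property
    def rotation_vector(self) -> np.ndarray:
        return matrix_to_rotvec(self.rotation)

    @property
    def euler(self) -> "EulerAngles":
        return matrix_to_euler_zyx(self.rotation)


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic Z-Y-X Euler angles in degrees; Z is the optical axis.

    ``yaw`` is the head angle about the vertical when the camera looks
    straight down.
    """

    yaw: float
    pitch: float
    roll: float


def _assert_rotation(R: np.ndarray, atol: float = 1e-6) -> None:
    if not np.allclose(R @ R.T, np.eye(3), atol=atol):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation matrix has negative determinant")


# --------------------------------------------------------------------------
# rotation representations

def rotvec_to_matrix(rotvec) -> np.ndarray:
    """Rodrigues formula: axis-angle vector -> rotation matrix."""
    v = np.asarray(rotvec, dtype=float).reshape(3)
    theta = np.linalg.norm(v)
    if theta < 1e-15:
        return np.eye(3)
    k = v / theta
    K = np.array([
        [0.0, -k[2], k[1]],
        [k[2], 0.0, -k[0]],
        [-k[1], k[0], 0.0],
    ])
    return np.eye(3) + math.sin(theta) * K + (1.0 - math.cos(theta)) * (K @ K)


def matrix_to_rotvec(R: np.ndarray) -> np.ndarray:
    """Inverse Rodrigues for rotation angles in [0, pi)."""
    R = np.asarray(R, dtype=float).reshape(3, 3)
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = math.acos(cos_theta)
    if theta < 1e-12:
        return np.zeros(3)
    if theta > math.pi - 1e-6:
        # near pi: axis from the symmetric part
        A = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.clip(np.diag(A), 0.0, None))
        # fix signs from off-diagonals
        i = int(np.argmax(axis))
        if axis[i] > 0:
            axis = A[:, i] / axis[i]
            axis = axis / np.linalg.norm(axis)
        return axis * theta
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return w / (2.0 * math.sin(theta)) * theta


def euler_zyx_to_matrix(yaw_deg: float, pitch_deg: float, roll_deg: float) -> np.ndarray:
    """Intrinsic Z-Y-X: R = Rz(yaw) @ Ry(pitch) @ Rx(roll)."""
    cy, sy = math.cos(math.radians(yaw_deg)), math.sin(math.radians(yaw_deg))
    cp, sp = math.cos(math.radians(pitch_deg)), math.sin(math.radians(pitch_deg))
    cr, sr = math.cos(math.radians(roll_deg)), math.sin(math.radians(roll_deg))
    Rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1.0]])
    Ry = np.array([[cp, 0, sp], [0, 1.0, 0], [-sp, 0, cp]])
    Rx = np.array([[1.0, 0, 0], [0, cr, -sr], [0, sr, cr]])
    return Rz @ Ry @ Rx


def matrix_to_euler_zyx(R: np.ndarray) -> EulerAngles:
    """Extract intrinsic Z-Y-X Euler angles; raises near gimbal lock."""
    R = np.asarray(R, dtype=float).reshape(3, 3)
    sp = -R[2, 0]
    if abs(sp) > math.sin(math.radians(89.0)):
        raise ValueError(
            "pitch within 1 degree of gimbal lock; yaw/roll are not separable "
            "for this pose — check marker/camera mounting"
        )
    pitch = math.asin(np.clip(sp, -1.0, 1.0))
    yaw = math.atan2(R[1, 0], R[0, 0])
    roll = math.atan2(R[2, 1], R[2, 2])
    return EulerAngles(math.degrees(yaw), math.degrees(pitch), math.degrees(roll))


# --------------------------------------------------------------------------
# forward projection

def project_marker_batch(rotations: np.ndarray, translations: np.ndarray,
                         marker: MarkerModel, camera: CameraModel) -> np.ndarray:
    """Project marker corners for N poses at once.

    Parameters are (N, 3, 3) rotations and (N, 3) translations; returns
    (N, 4, 2) pixel coordinates.  Raises if any corner lies behind the
    camera (z <= 0).
    """
    R = np.asarray(rotations, dtype=float).reshape(-1, 3, 3)
    t = np.asarray(translations, dtype=float).reshape(-1, 3)
    obj = marker.corners_object()  # (4, 3)
    cam_pts = np.einsum("nij,kj->nki", R, obj) + t[:, None, :]  # (N, 4, 3)
    z = cam_pts[..., 2]
    if np.any(z <= 0):
        raise ValueError("marker corner behind camera (z <= 0)")
    f = camera.focal_length
    px, py = camera.principal_point
    uv = np.empty(cam_pts.shape[:2] + (2,))
    uv[..., 0] = px + f * cam_pts[..., 0] / z
    uv[..., 1] = py + f * cam_pts[..., 1] / z
    return uv


def project_marker(pose: PoseEstimate, marker: MarkerModel, camera: CameraModel,
                   timestamp: float = 0.0) -> MarkerObservation:
    """Project the marker through the ideal pinhole model.

    Corner order is preserved.  A corner behind the camera yields an invalid
    observation carrying a diagnostic instead of raising.
    """
    try:
        uv = project_marker_batch(pose.rotation[None], pose.translation[None],
                                  marker, camera)[0]
    except ValueError as exc:
        return MarkerObservation(timestamp, np.full((4, 2), np.nan),
                                 valid=False, message=str(exc))
    return MarkerObservation(timestamp, uv, valid=True)


# --------------------------------------------------------------------------
# planar pose from 4 corners (DLT homography + decomposition)

_COND_THRESHOLD = 1e8


def _homographies(corners: np.ndarray, marker: MarkerModel,
                  camera: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Solve the 4-point DLT per observation.

    ``corners`` is (N, 4, 2); returns (N, 3, 3) homographies mapping
    marker-plane meters to normalized image coordinates, plus the (N,)
    condition numbers of the DLT systems.
    """
    N = corners.shape[0]
    obj = marker.corners_object()[:, :2]  # (4, 2) meters
    f = camera.focal_length
    px, py = camera.principal_point
    xn = (corners[..., 0] - px) / f  # (N, 4)
    yn = (corners[..., 1] - py) / f

    A = np.zeros((N, 8, 8))
    b = np.empty((N, 8))
    X, Y = obj[:, 0], obj[:, 1]  # (4,)
    for k in range(4):
        r = 2 * k
        A[:, r, 0] = X[k]
        A[:, r, 1] = Y[k]
        A[:, r, 2] = 1.0
        A[:, r, 6] = -xn[:, k] * X[k]
        A[:, r, 7] = -xn[:, k] * Y[k]
        b[:, r] = xn[:, k]
        A[:, r + 1, 3] = X[k]
        A[:, r + 1, 4] = Y[k]
        A[:, r + 1, 5] = 1.0
        A[:, r + 1, 6] = -yn[:, k] * X[k]
        A[:, r + 1, 7] = -yn[:, k] * Y[k]
        b[:, r + 1] = yn[:, k]

    sv = np.linalg.svd(A, compute_uv=False)  # (N, 8)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = sv[:, 0] / sv[:, -1]
    degenerate = ~np.isfinite(cond)
    if np.any(degenerate):
        # keep solve from raising; flagged downstream
        A[degenerate] = np.eye(8)
        b[degenerate] = 0.0
    h = np.linalg.solve(A, b[..., None])[..., 0]  # (N, 8)
    H = np.concatenate([h, np.ones((N, 1))], axis=1).reshape(N, 3, 3)
    cond = np.where(degenerate, np.inf, cond)
    return H, cond


def estimate_planar_pose_batch(corners: np.ndarray, marker: MarkerModel,
                               camera: CameraModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recover (rotations, translations, low_confidence) for (N, 4, 2) corners.

    The first two rotation columns come from the scaled homography columns,
    the third from their cross product; the result is projected onto the
    nearest rotation (polar decomposition via SVD).  Translation is metric
    because the marker model is metric.
    """
    corners = np.asarray(corners, dtype=float).reshape(-1, 4, 2)
    H, cond = _homographies(corners, marker, camera)
    h1, h2, h3 = H[:, :, 0], H[:, :, 1], H[:, :, 2]
    lam = 2.0 / (np.linalg.norm(h1, axis=1) + np.linalg.norm(h2, axis=1))
    r1 = h1 * lam[:, None]
    r2 = h2 * lam[:, None]
    r3 = np.cross(r1, r2)
    Rraw = np.stack([r1, r2, r3], axis=2)  # columns
    U, _, Vt = np.linalg.svd(Rraw)
    det = np.linalg.det(U @ Vt)
    D = np.zeros_like(Rraw)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = det
    R = U @ D @ Vt
    t = h3 * lam[:, None]
    low_conf = cond > _COND_THRESHOLD
    return R, t, low_conf


def _quad_is_degenerate(corners: np.ndarray, tol: float = 1e-9) -> bool:
    """True if any three of the four corners are (near-)collinear."""
    c = corners
    for i in range(4):
        idx = [k for k in range(4) if k != i]
        a, bb, cc = c[idx[0]], c[idx[1]], c[idx[2]]
        area2 = abs((bb[0] - a[0]) * (cc[1] - a[1]) - (bb[1] - a[1]) * (cc[0] - a[0]))
        if area2 < tol:
            return True
    return False


def estimate_planar_pose(obs: MarkerObservation, marker: MarkerModel,
                         camera: CameraModel) -> PoseEstimate:
    """Planar pose of the marker from one 4-corner observation."""
    if not obs.valid:
        raise ValueError("cannot estimate pose from an invalid observation")
    if _quad_is_degenerate(obs.corners):
        raise ValueError("degenerate marker observation: collinear corners")
    R, t, low = estimate_planar_pose_batch(obs.corners[None], marker, camera)
    return PoseEstimate(R[0], t[0], low_confidence=bool(low[0]))


def pose_to_head_yaw(pose: PoseEstimate, reference_yaw: float = 0.0) -> float:
    """Head angle H in degrees: marker yaw about the optical axis minus the
    reference yaw, wrapped to (-180, 180].

    The reference yaw is taken from the fixation of the zero landmark at the
    start of a recording.  Positive H means the head rotated in the positive
    image-rotation direction; the simulator and pipeline share this sign
    convention so that G = E + H + c holds sign-correctly.
    """
    yaw = pose.euler.yaw
    return float(wrap_degrees(yaw - reference_yaw))
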