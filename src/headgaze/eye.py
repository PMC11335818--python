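"""Scene-camera pixel to eye-in-head angle conversion.

A wearable eye tracker reports the gaze point as a pixel coordinate in its
scene-camera image.  Under the ideal pinhole model the horizontal eye-in-head
angle of pixel x is atan((cx - x)/f): the sign is flipped so that positive
azimuth means the eye rotated toward the wearer's left (gaze point moves left
in the image, toward smaller x).  The mapping is a tangent, not a linear
scale, which matters toward the edge of the ~82 degree field of view.
"""

from __future__ import annotations

import numpy as np

from .geometry import CameraModel

__all__ = ["pixels_to_angles", "angles_to_pixels"]


def pixels_to_angles(x, y, camera: CameraModel):
    """Convert scene-camera pixels to (azimuth, elevation) in degrees.

    Positive azimuth = left, positive elevation = up.  Accepts scalars or
    arrays.  NaN input propagates to NaN output.
    """
    if camera is None:
        raise ValueError("a scene-camera model is required")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    px, py = camera.principal_point
    f = camera.focal_length
    azimuth = np.degrees(np.arctan2(px - x, f))
    elevation = np.degrees(np.arctan2(py - y, f))
    if azimuth.ndim == 0:
        return float(azimuth), float(elevation)
    return azimuth, elevation


def angles_to_pixels(azimuth, elevation, camera: CameraModel):
    """Exact inverse of :func:`pixels_to_angles` (used by the simulator)."""
    az = np.radians(np.asarray(azimuth, dtype=float))
    el = np.radians(np.asarray(elevation, dtype=float))
    px, py = camera.principal_point
    f = camera.focal_length
    x = px - f * np.tan(az)
    y = py - f * np.tan(el)
    if x.ndim == 0:
        return float(x), float(y)
    return x, y
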