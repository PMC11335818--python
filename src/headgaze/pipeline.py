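"""End-to-end processing: raw marker + eye streams -> calibrated gaze record,
quality report, and gaze-shift events.

This is the measurement path.  It consumes only raw observations and the
hand-segmentation annotations (fixation windows, oscillation episodes,
condition spans) — never simulator ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from . import fusion, quality
from .eye import pixels_to_angles
from .geometry import (CameraModel, MarkerModel, estimate_planar_pose_batch,
                       matrix_to_euler_zyx, wrap_degrees)
from .signals import SampledSignal

__all__ = ["ProcessedSession", "marker_to_yaw", "process_session"]


@dataclass
class ProcessedSession:
    record: fusion.GazeRecord
    calibration: fusion.CalibrationResult
    sync_offset: float
    events: list
    summary: ev.CoordinationSummary | None
    quality: quality.QualityReport
    head_signal: SampledSignal
    eye_signal: SampledSignal


def marker_to_yaw(marker_df: pd.DataFrame, marker: MarkerModel,
                  camera: CameraModel) -> pd.DataFrame:
    """Per-frame marker pose -> Euler angles and translation.

    Returns a dataframe with columns timestamp, yaw_deg, pitch_deg, roll_deg,
    tx_m, ty_m, tz_m, valid.  Low-confidence poses are flagged invalid.
    """
    cols = [f"{a}{k}" for k in range(4) for a in ("x", "y")]
    corners = marker_df[cols].to_numpy(dtype=float).reshape(-1, 4, 2)
    valid_in = marker_df["valid"].to_numpy(dtype=bool) if "valid" in marker_df else \
        np.ones(len(marker_df), dtype=bool)
    R, t, low = estimate_planar_pose_batch(corners, marker, camera)
    n = len(marker_df)
    yaw = np.full(n, np.nan)
    pitch = np.full(n, np.nan)
    roll = np.full(n, np.nan)
    ok = valid_in & ~low & np.all(np.isfinite(corners.reshape(n, -1)), axis=1)
    # vectorized Z-Y-X extraction (poses near gimbal lock flagged invalid)
    sp = -R[:, 2, 0]
    lockfree = np.abs(sp) < np.sin(np.radians(89.0))
    ok &= lockfree
    yaw[ok] = np.degrees(np.arctan2(R[ok, 1, 0], R[ok, 0, 0]))
    pitch[ok] = np.degrees(np.arcsin(np.clip(sp[ok], -1, 1)))
    roll[ok] = np.degrees(np.arctan2(R[ok, 2, 1], R[ok, 2, 2]))
    return pd.DataFrame({
        "timestamp": marker_df["timestamp"].to_numpy(dtype=float),
        "yaw_deg": yaw,
        "pitch_deg": pitch,
        "roll_deg": roll,
        "tx_m": t[:, 0],
        "ty_m": t[:, 1],
        "tz_m": t[:, 2],
        "valid": ok.astype(int),
    })


def _central_windows(fixations, fraction=0.5):
    wins, targets = [], []
    for fx in fixations:
        wins.append(fusion.central_window(fx["t0"], fx["t1"], fraction))
        targets.append(fx["azimuth_deg"])
    return wins, targets


def process_session(marker_df: pd.DataFrame, eye_df: pd.DataFrame,
                    annotations: dict,
                    ceiling_camera: CameraModel, scene_camera: CameraModel,
                    marker: MarkerModel,
                    rate: float = fusion.DEFAULT_RATE_HZ,
                    sync_search: float = 1.0,
                    skip_sync: bool = False) -> ProcessedSession:
    """Run the full measurement pipeline on one recording."""
    # 1. head orientation from marker poses
    pose = marker_to_yaw(marker_df, marker, ceiling_camera)
    yaw = pose["yaw_deg"].to_numpy()
    t_head = pose["timestamp"].to_numpy()
    ok_head = pose["valid"].to_numpy(dtype=bool)
    w0, w1 = annotations["corner_window"]
    ref_mask = (t_head >= w0) & (t_head <= w1) & ok_head
    if not np.any(ref_mask):
        raise ValueError("no valid poses inside the corner-fixation window")
    reference_yaw = float(np.median(yaw[ref_mask]))
    H_vals = wrap_degrees(yaw - reference_yaw)
    head_sig = SampledSignal(t_head, np.where(ok_head, H_vals, np.nan), ok_head)

    # 2. eye-in-head angles from scene pixels
    az, _el = pixels_to_angles(eye_df["x_px"].to_numpy(dtype=float),
                               eye_df["y_px"].to_numpy(dtype=float),
                               scene_camera)
    ok_eye = eye_df["valid"].to_numpy(dtype=bool) if "valid" in eye_df else \
        np.ones(len(eye_df), dtype=bool)
    raw_t_eye = eye_df["timestamp"].to_numpy(dtype=float)
    eye_sig = SampledSignal(raw_t_eye, np.where(ok_eye, az, np.nan), ok_eye)

    # 3. clock synchronization on the first oscillation episode
    offset = 0.0
    if not skip_sync:
        if not annotations.get("oscillations"):
            import warnings
            warnings.warn("no oscillation episode annotated; proceeding with "
                          "offset 0", stacklevel=2)
        else:
            t0, t1 = annotations["oscillations"][0]
            pad = sync_search + 0.5
            e_seg = eye_sig.slice_time(t0 - pad, t1 + pad)
            h_seg = head_sig.slice_time(t0, t1)
            offset = fusion.synchronize(e_seg, h_seg, search_window=sync_search)
    eye_aligned = eye_sig.shifted(offset)

    # 4. resample both to the analysis rate and fuse
    t_lo = max(eye_aligned.timestamps[0], head_sig.timestamps[0])
    t_hi = min(eye_aligned.timestamps[-1], head_sig.timestamps[-1])
    E_u = fusion.resample_to_rate(eye_aligned, rate, start=t_lo, stop=t_hi)
    H_u = fusion.resample_to_rate(head_sig, rate, start=E_u.timestamps[0],
                                  stop=E_u.timestamps[-1])
    n = min(len(E_u), len(H_u))
    E_u = SampledSignal(E_u.timestamps[:n], E_u.values[:n], E_u.valid[:n])
    H_u = SampledSignal(H_u.timestamps[:n], H_u.values[:n], H_u.valid[:n])
    record0 = fusion.fuse(E_u, H_u, c=0.0)

    # 5. calibration constant from the sweep fixations
    wins, targets = _central_windows(annotations["calibration_fixations"])
    cal = fusion.calibrate_constant(record0, wins, targets)
    record = record0.with_constant(cal.c)

    # 6. quality metrics (accuracy on the calibrated record)
    qrep = quality.quality_report(record, wins, targets,
                                  raw_t_eye, ok_eye)

    # 7. event segmentation + condition labels + summary
    evs = ev.detect_gaze_saccades(record)
    for e in evs:
        e.condition = _label_for(e.saccade_onset, annotations.get("conditions", []))
    labeled = [e for e in evs if e.condition]
    summary = None
    try:
        summary = ev.coordination_summary(labeled)
    except ValueError:
        pass
    return ProcessedSession(record, cal, offset, evs, summary, qrep,
                            head_sig, eye_sig)


def _label_for(t: float, conditions: list[dict]) -> str:
    for c in conditions:
        if c["t0"] <= t <= c["t1"]:
            return c["label"]
    return ""
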