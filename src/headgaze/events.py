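"""Segmentation and analysis of combined eye-head gaze shifts.

During large gaze shifts the vestibulo-ocular reflex is suppressed while the
saccade runs, and re-engages afterwards so that continuing head rotation
leaves gaze stationary.  Gaze velocity therefore isolates the saccadic phase
cleanly: it is near zero outside saccades even when the head is moving fast.
Detection thresholds the gaze velocity and refines each event's bounds
outward to a fraction of its own peak.

The relative-timing analysis compares mean eye and head velocities in the
100 ms before versus the 100 ms after saccade onset: an active VOR before
onset (eye and head velocities opposite) together with same-sign head
velocity across onset marks a head movement that was launched before the
saccade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .fusion import GazeRecord

__all__ = [
    "GazeShiftEvent",
    "CoordinationSummary",
    "smoothed_velocity",
    "detect_gaze_saccades",
    "vor_phase",
    "pre_post_velocities",
    "classify_head_lead",
    "coordination_summary",
    "events_to_dataframe",
]

# detection defaults (config-exposed; the source papers give no algorithm)
VELOCITY_THRESHOLD_DPS = 50.0
ONSET_PEAK_FRACTION = 0.10
REFINE_FLOOR_DPS = 15.0
MERGE_GAP_S = 0.050
MIN_AMPLITUDE_DEG = 5.0
HEAD_STILL_DPS = 10.0
SMOOTH_WINDOW_SAMPLES = 5
VOR_GUARD_S = 0.025          # skip smoothing spill-over after saccade offset
VOR_MIN_DURATION_S = 0.050
PRE_POST_WINDOW_S = 0.100
EPOCH_SPAN_S = (-0.250, 0.750)
HEAD_LEAD_MIN_DPS = 5.0


@dataclass
class GazeShiftEvent:
    saccade_onset: float
    saccade_offset: float
    gaze_amplitude: float          # signed, degrees
    saccade_amplitude: float       # signed eye-in-head displacement
    head_amplitude: float          # signed head displacement over the saccade
    peak_gaze_velocity: float      # magnitudes, deg/s
    peak_eye_velocity: float
    peak_head_velocity: float      # over the whole head-movement interval
    saccade_duration: float
    head_movement_start: float
    head_movement_end: float
    head_movement_duration: float
    pre_eye_vel: float = np.nan
    pre_head_vel: float = np.nan
    post_eye_vel: float = np.nan
    post_head_vel: float = np.nan
    vor_start: float = np.nan
    vor_end: float = np.nan
    vor_gain: float = np.nan
    head_lead: bool = False
    timing_valid: bool = False
    condition: str = ""

    @property
    def onset_index(self):  # convenience for tests
        return None


@dataclass
class CoordinationSummary:
    per_condition: pd.DataFrame
    head_velocity_slope: float          # 1/s, through the origin
    head_leads_fraction: float
    saccade_sublinear: bool
    n_events: int

    def to_dict(self) -> dict:
        return {
            "per_condition": self.per_condition.reset_index().to_dict(orient="records"),
            "head_velocity_slope_per_s": float(self.head_velocity_slope),
            "head_leads_fraction": float(self.head_leads_fraction),
            "saccade_sublinear": bool(self.saccade_sublinear),
            "n_events": int(self.n_events),
        }


# --------------------------------------------------------------------------

def smoothed_velocity(values: np.ndarray, dt: float,
                      window: int = SMOOTH_WINDOW_SAMPLES) -> np.ndarray:
    """Central-difference velocity after a local-quadratic smoother."""
    v = np.asarray(values, dtype=float)
    if window >= 5 and len(v) > window:
        v = savgol_filter(v, window, polyorder=2)
    return np.gradient(v, dt)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _head_interval(record: GazeRecord, dH: np.ndarray, i_on: int, i_off: int,
                   still: float = HEAD_STILL_DPS) -> tuple[int, int]:
    """Head-movement [start, end] indices around a saccade."""
    n = len(dH)
    i0 = i_on
    while i0 > 0 and abs(dH[i0 - 1]) >= still:
        i0 -= 1
    i1 = i_off
    while i1 < n - 1 and abs(dH[i1 + 1]) >= still:
        i1 += 1
    return i0, i1


def detect_gaze_saccades(record: GazeRecord,
                         threshold: float = VELOCITY_THRESHOLD_DPS,
                         peak_fraction: float = ONSET_PEAK_FRACTION,
                         merge_gap: float = MERGE_GAP_S,
                         min_amplitude: float = MIN_AMPLITUDE_DEG,
                         smooth_window: int = SMOOTH_WINDOW_SAMPLES,
                         ) -> list[GazeShiftEvent]:
    """Detect gaze saccades by thresholding gaze velocity.

    Candidate intervals where |dG| exceeds ``threshold`` are refined outward
    to where |dG| falls below ``peak_fraction`` of that event's own peak (but
    never below an absolute floor, so small events with a moving head at
    onset refine all the way to the velocity step where the VOR disengages),
    merged when closer than ``merge_gap`` seconds, and discarded when the
    gaze displacement is below ``min_amplitude`` degrees.
    """
    if record.dG is None:
        raise ValueError("record has no velocities")
    dt = record.dt
    dG = smoothed_velocity(record.G, dt, smooth_window)
    dE = smoothed_velocity(record.E, dt, smooth_window)
    dH = smoothed_velocity(record.H, dt, smooth_window)
    speed = np.abs(dG)
    # bound refinement uses a sharper velocity (3-tap-averaged raw central
    # difference): the polynomial smoother spreads the onset/offset velocity
    # step over +/-2 samples, which would bias the refined bounds
    kernel = np.ones(3) / 3.0
    speed_ref = np.abs(np.convolve(np.gradient(record.G, dt), kernel,
                                   mode="same"))
    intervals = []
    for s, e in _runs(speed > threshold):
        peak = speed[s:e].max()
        # the refinement level tracks the event's own peak but is bounded
        # below by an absolute floor (well above velocity noise) and above by
        # the VOR-disengagement step of small events
        low = min(peak_fraction * peak,
                  max(REFINE_FLOOR_DPS, 0.04 * peak))
        i0, i1 = s, e - 1
        while i0 > 0 and speed_ref[i0 - 1] >= low:
            i0 -= 1
        while i1 < len(speed_ref) - 1 and speed_ref[i1 + 1] >= low:
            i1 += 1
        intervals.append([i0, i1])
    # merge
    merged: list[list[int]] = []
    gap = int(round(merge_gap / dt))
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], iv[1])
        else:
            merged.append(iv)
    events = []
    t = record.time
    for i0, i1 in merged:
        amp = record.G[i1] - record.G[i0]
        if abs(amp) < min_amplitude:
            continue
        h0, h1 = _head_interval(record, dH, i0, i1)
        # sub-sample onset: interpolate where the refinement velocity crossed
        # the refinement level between the last outside and first inside
        # sample (amplitudes still use the grid samples)
        peak = speed[i0:i1 + 1].max()
        low = min(peak_fraction * peak, max(REFINE_FLOOR_DPS, 0.04 * peak))
        t_on = float(t[i0])
        if i0 > 0 and speed_ref[i0] > low and speed_ref[i0] > speed_ref[i0 - 1]:
            frac = (speed_ref[i0] - low) / (speed_ref[i0] - speed_ref[i0 - 1])
            t_on -= dt * float(np.clip(frac, 0.0, 0.85))
        # amplitudes from the flanking samples: gaze is VOR-stabilized just
        # outside the event, so this recovers the sub-sample displacement the
        # grid-quantized bounds would clip.  Same endpoints for E/H/G keep
        # the additive decomposition exact.
        j0, j1 = max(i0 - 1, 0), min(i1 + 1, len(t) - 1)
        amp = record.G[j1] - record.G[j0]
        ev = GazeShiftEvent(
            saccade_onset=t_on,
            saccade_offset=float(t[i1]),
            gaze_amplitude=float(amp),
            saccade_amplitude=float(record.E[j1] - record.E[j0]),
            head_amplitude=float(record.H[j1] - record.H[j0]),
            peak_gaze_velocity=float(np.abs(dG[i0:i1 + 1]).max()),
            peak_eye_velocity=float(np.abs(dE[i0:i1 + 1]).max()),
            peak_head_velocity=float(np.abs(dH[h0:h1 + 1]).max()),
            saccade_duration=float(t[i1] - t[i0]),
            head_movement_start=float(t[h0]),
            head_movement_end=float(t[h1]),
            head_movement_duration=float(t[h1] - t[h0]),
        )
        vor_phase(record, ev, dE=dE, dH=dH)
        pre_post_velocities(record, ev, dE=dE, dH=dH)
        ev.head_lead = classify_head_lead(ev)
        events.append(ev)
    return events


def vor_phase(record: GazeRecord, event: GazeShiftEvent,
              still: float = HEAD_STILL_DPS,
              guard: float = VOR_GUARD_S,
              min_duration: float = VOR_MIN_DURATION_S,
              dE: np.ndarray | None = None,
              dH: np.ndarray | None = None) -> tuple[float, float] | None:
    """VOR interval after the saccade and the eye-head velocity gain.

    The interval runs from the saccade offset until |head velocity| drops
    below ``still``; within it the gain g = -mean(dE)/mean(dH).  A guard of
    ``guard`` seconds after the offset is excluded from the gain average so
    the velocity smoother's spill-over from the saccade does not bias it.
    Returns None (and leaves NaN fields) when the head is already stationary
    at the saccade offset or the phase is shorter than ``min_duration``.
    """
    dt = record.dt
    if dE is None:
        dE = smoothed_velocity(record.E, dt)
    if dH is None:
        dH = smoothed_velocity(record.H, dt)
    t = record.time
    i_off = int(np.searchsorted(t, event.saccade_offset))
    i_end = int(np.searchsorted(t, event.head_movement_end))
    if i_end <= i_off or abs(dH[min(i_off, len(dH) - 1)]) < still:
        return None
    t0, t1 = t[i_off], t[i_end]
    if t1 - t0 < min_duration:
        return None
    j0 = int(np.searchsorted(t, t0 + guard))
    if j0 >= i_end:
        j0 = i_off
    mh = float(np.mean(dH[j0:i_end + 1]))
    me = float(np.mean(dE[j0:i_end + 1]))
    if mh == 0:
        return None
    event.vor_start = float(t0)
    event.vor_end = float(t1)
    event.vor_gain = -me / mh
    return (float(t0), float(t1))


def pre_post_velocities(record: GazeRecord, event: GazeShiftEvent,
                        window: float = PRE_POST_WINDOW_S,
                        dE: np.ndarray | None = None,
                        dH: np.ndarray | None = None) -> tuple:
    """Mean eye and head velocities in the 100 ms before/after saccade onset.

    pre covers [onset - window, onset); post covers [onset, onset + window].
    Events without enough context on either side are flagged
    ``timing_valid = False`` and excluded from summaries.
    """
    dt = record.dt
    if dE is None:
        dE = smoothed_velocity(record.E, dt)
    if dH is None:
        dH = smoothed_velocity(record.H, dt)
    t = record.time
    on = event.saccade_onset
    if on - window < t[0] or on + window > t[-1]:
        event.timing_valid = False
        return (np.nan, np.nan, np.nan, np.nan)
    pre = (t >= on - window) & (t < on)
    post = (t >= on) & (t <= on + window)
    event.pre_eye_vel = float(np.mean(dE[pre]))
    event.pre_head_vel = float(np.mean(dH[pre]))
    event.post_eye_vel = float(np.mean(dE[post]))
    event.post_head_vel = float(np.mean(dH[post]))
    event.timing_valid = True
    return (event.pre_eye_vel, event.pre_head_vel,
            event.post_eye_vel, event.post_head_vel)


def analysis_epoch(record: GazeRecord, event: GazeShiftEvent,
                   span: tuple[float, float] = EPOCH_SPAN_S) -> GazeRecord:
    """The [-250, +750] ms per-event epoch around saccade onset (for plots
    and the wider-interval velocity averages)."""
    t0 = event.saccade_onset + span[0]
    t1 = event.saccade_onset + span[1]
    m = (record.time >= t0) & (record.time <= t1)
    return GazeRecord(record.time[m], record.E[m], record.H[m], record.G[m],
                      record.dE[m], record.dH[m], record.dG[m],
                      record.valid[m], record.rate, record.c)


def classify_head_lead(event: GazeShiftEvent,
                       min_vel: float = HEAD_LEAD_MIN_DPS) -> bool:
    """True when the head was already moving, in the saccade's direction,
    before saccade onset."""
    if not event.timing_valid or not np.isfinite(event.pre_head_vel):
        return False
    return (abs(event.pre_head_vel) > min_vel
            and np.sign(event.pre_head_vel) == np.sign(event.post_head_vel))


def events_to_dataframe(events: list[GazeShiftEvent]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in events])


def coordination_summary(events: list[GazeShiftEvent],
                         min_events_per_condition: int = 3) -> CoordinationSummary:
    """Per-condition means +/- SEM and the head-velocity main-sequence slope.

    The slope is the least-squares fit through the origin of per-event peak
    head velocity against gaze amplitude (magnitudes).  Sublinearity of the
    saccade contribution is flagged when the saccade/gaze amplitude ratio
    decreases across conditions ordered by gaze amplitude.
    """
    labeled = [e for e in events if e.condition]
    if not labeled:
        labeled = events
    df = events_to_dataframe(labeled)
    if df.empty:
        raise ValueError("no events to summarize")
    df["abs_gaze"] = df["gaze_amplitude"].abs()
    df["abs_saccade"] = df["saccade_amplitude"].abs()
    counts = df.groupby("condition").size()
    deficient = counts[counts < min_events_per_condition]
    if len(counts) < 2 or len(deficient):
        raise ValueError(
            "too few events per condition: "
            + ", ".join(f"{k}={v}" for k, v in counts.items())
        )

    def sem(x):
        return x.std(ddof=1) / np.sqrt(len(x))

    agg = df.groupby("condition").agg(
        n=("abs_gaze", "size"),
        gaze_amplitude_mean=("abs_gaze", "mean"),
        gaze_amplitude_sem=("abs_gaze", sem),
        saccade_amplitude_mean=("abs_saccade", "mean"),
        saccade_amplitude_sem=("abs_saccade", sem),
        peak_saccade_velocity_mean=("peak_eye_velocity", "mean"),
        peak_saccade_velocity_sem=("peak_eye_velocity", sem),
        saccade_duration_mean=("saccade_duration", "mean"),
        saccade_duration_sem=("saccade_duration", sem),
        peak_head_velocity_mean=("peak_head_velocity", "mean"),
        peak_head_velocity_sem=("peak_head_velocity", sem),
    ).sort_values("gaze_amplitude_mean")

    a = df["abs_gaze"].to_numpy()
    v = df["peak_head_velocity"].to_numpy()
    slope = float(np.sum(v * a) / np.sum(a * a))

    timed = df[df["timing_valid"]]
    frac = float(timed["head_lead"].mean()) if len(timed) else float("nan")

    ratio = (agg["saccade_amplitude_mean"] / agg["gaze_amplitude_mean"]).to_numpy()
    sublinear = bool(len(ratio) >= 2 and np.all(np.diff(ratio) < 1e-9))

    return CoordinationSummary(
        per_condition=agg,
        head_velocity_slope=slope,
        head_leads_fraction=frac,
        saccade_sublinear=sublinear,
        n_events=len(df),
    )
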