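"""Kinematic simulator of combined eye-head gaze shifts.

Generates ground-truth recordings of the measurement protocol — a
calibration sweep over wall targets, head-oscillation synchronization
episodes, and blocks of large alternating gaze shifts — and renders them
into the exact raw formats the processing pipeline consumes: fiducial-marker
corner pixels from a downward ceiling camera and scene-camera gaze pixels
from the wearable tracker, with realistic sampling (bimodal eye-tracker
intervals), sensor noise, a clock offset between the two devices, and a
nonzero additive gaze constant.

Movement anatomy per shift: both effectors follow raised-cosine (bell)
velocity profiles.  The head starts ``head_lead`` seconds before the
saccade; its peak velocity is proportional to the gaze amplitude
(``head_velocity_slope``).  The saccadic eye-in-head amplitude follows a
saturating sharing rule (nearly the whole gaze amplitude for small shifts, a
diminishing share beyond a break point, hard-capped at the oculomotor
limit), with peak velocity from a saturating main-sequence curve.  Outside
the saccade interval the eye counter-rotates at ``vor_gain`` times head
velocity, so with gain 1 gaze is perfectly stable whenever no saccade is in
flight.  The head amplitude is solved so the gaze lands exactly on the
requested amplitude.

The simulator and the processing pipeline are independent code paths: the
pipeline never reads the truth except in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import geometry
from .eye import angles_to_pixels

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimSession",
    "simulate_gaze_shift",
    "simulate_oscillation",
    "simulate_session",
]

PAPER_SEPARATIONS = (17.6, 38.3, 63.3, 91.2, 118.9, 143.6)


# --------------------------------------------------------------------------
# configuration

@dataclass
class SimConfig:
    target_separations: tuple = PAPER_SEPARATIONS
    shifts_per_condition: int = 45
    head_lead: float = 0.120                 # s; negative = eye leads
    head_velocity_slope: float = 2.31        # 1/s, peak head vel / gaze amp
    saccade_vmax: float = 650.0              # deg/s main-sequence ceiling
    saccade_a63: float = 16.0                # deg main-sequence scale
    saccade_amplitude_cap: float = 80.0      # deg oculomotor limit
    eye_share_mode: str = "auto"             # "auto": solve the saccade
    # amplitude from the re-centering condition (post-saccadic VOR returns
    # the eye to the orbit center); "piecewise": use the explicit rule below
    eye_share_break: float = 35.0            # deg: full-share region end
    eye_share_full: float = 0.90             # share below the break
    eye_share_beyond: float = 0.70           # marginal share above the break
    vor_gain: float = 1.0
    eye_noise_sd: float = 0.05               # deg
    head_noise_sd: float = 0.02              # deg (on marker yaw)
    eye_interval_modes_ms: tuple = (4.0, 8.0)
    eye_interval_sds_ms: tuple = (0.08, 0.08)
    eye_effective_rate_hz: float = 200.54    # sets the mixture weights
    head_rate: float = 250.0                 # Hz ceiling camera
    calibration_constant_true: float = 0.5   # deg, the constant c; kept small
    # by default so 80-deg saccades stay inside the scene camera's 82-deg FOV
    sync_offset_true: float = 0.137          # s eye clock ahead of head clock
    oscillation_amplitude: float = 10.0      # deg
    oscillation_frequency: float = 1.0       # Hz
    oscillation_cycles: int = 5
    recenter_duration: float = 0.30          # s VOR-compensated re-centering
    pre_shift_hold: float = 1.00             # s stationary before each shift
    post_shift_hold: float = 0.80            # s stationary after each shift
    # holds are long enough that most sliding precision windows fall in
    # stationary stretches, as in self-paced fixation behavior
    marker_side: float = 0.10                # m
    marker_distance: float = 1.0             # m below the ceiling camera
    marker_mount_yaw: float = 20.0           # deg marker-vs-head offset
    seed: int = 0

    def __post_init__(self):
        for s in self.target_separations:
            if not 0.0 < s < 220.0:
                raise ValueError("target separations must lie in (0, 220) deg")
        if self.saccade_amplitude_cap > 80.0:
            raise ValueError("saccade amplitude cap exceeds the oculomotor limit")
        if not 0.0 < self.eye_interval_weight_fast() < 1.0:
            raise ValueError("eye_effective_rate_hz incompatible with interval modes")

    def eye_interval_weight_fast(self) -> float:
        """Weight of the fast interval mode reproducing the requested
        effective sampling rate."""
        m1, m2 = self.eye_interval_modes_ms
        mean_ms = 1000.0 / self.eye_effective_rate_hz
        return (m2 - mean_ms) / (m2 - m1)

    def eye_share(self, amplitude: float) -> float:
        """Saccadic (eye-in-head) amplitude for a given gaze amplitude."""
        a = abs(amplitude)
        if a <= self.eye_share_break:
            e = self.eye_share_full * a
        else:
            e = (self.eye_share_full * self.eye_share_break
                 + self.eye_share_beyond * (a - self.eye_share_break))
        return min(e, self.saccade_amplitude_cap)

    def saccade_peak_velocity(self, amplitude: float) -> float:
        """Main sequence: V = Vmax * (1 - exp(-A / A63))."""
        return self.saccade_vmax * (1.0 - math.exp(-abs(amplitude) / self.saccade_a63))


# --------------------------------------------------------------------------
# raised-cosine kinematics

def _bell_frac(u):
    """Displacement fraction of a raised-cosine velocity bell at phase u."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


class _Segment:
    """Piecewise-analytic E(t), H(t) over [t0, t0 + duration]."""

    t0: float
    duration: float
    E0: float
    H0: float

    def E(self, tau):
        raise NotImplementedError

    def H(self, tau):
        raise NotImplementedError

    @property
    def end_E(self) -> float:
        return float(self.E(np.asarray([self.duration]))[0])

    @property
    def end_H(self) -> float:
        return float(self.H(np.asarray([self.duration]))[0])


class HoldSegment(_Segment):
    def __init__(self, t0, E0, H0, duration):
        self.t0, self.E0, self.H0, self.duration = t0, E0, H0, duration

    def E(self, tau):
        return np.full_like(np.asarray(tau, dtype=float), self.E0)

    def H(self, tau):
        return np.full_like(np.asarray(tau, dtype=float), self.H0)


class RecenterSegment(_Segment):
    """Slow VOR-compensated eye re-centering: gaze stays put while the head
    takes over eccentricity (visually guided, gain exactly 1)."""

    def __init__(self, t0, E0, H0, target_E, duration):
        self.t0, self.E0, self.H0, self.duration = t0, E0, H0, duration
        self.dE = target_E - E0

    def E(self, tau):
        return self.E0 + self.dE * _bell_frac(np.asarray(tau, dtype=float) / self.duration)

    def H(self, tau):
        return self.H0 - self.dE * _bell_frac(np.asarray(tau, dtype=float) / self.duration)


class OscillationSegment(_Segment):
    """Sinusoidal head shake under fixation: E mirrors H exactly."""

    def __init__(self, t0, E0, H0, amplitude, frequency, cycles):
        self.t0, self.E0, self.H0 = t0, E0, H0
        self.amplitude, self.frequency = amplitude, frequency
        self.duration = cycles / frequency

    def _osc(self, tau):
        return self.amplitude * np.sin(2.0 * np.pi * self.frequency
                                       * np.asarray(tau, dtype=float))

    def E(self, tau):
        return self.E0 - self._osc(tau)

    def H(self, tau):
        return self.H0 + self._osc(tau)


class GazeShiftSegment(_Segment):
    """One combined eye-head gaze shift; local time 0 = head-movement start."""

    def __init__(self, t0, E0, H0, amplitude, cfg: SimConfig):
        self.t0, self.E0, self.H0 = t0, E0, H0
        self.cfg = cfg
        self.amp = float(amplitude)
        s = math.copysign(1.0, amplitude)
        A = abs(amplitude)
        g = cfg.vor_gain
        lead = cfg.head_lead  # >= 0: head first; < 0: saccade first
        Vh = cfg.head_velocity_slope * A

        if cfg.eye_share_mode == "auto":
            A_e, A_h = self._solve_amplitudes(A, lead, Vh, g)
        else:
            A_e = cfg.eye_share(A)
            if A - A_e < 1e-9 and abs(g - 1.0) < 1e-12:
                A_h = 0.0
            else:
                A_h = self._solve_head(A, A_e, self._saccade_duration(A_e),
                                       lead, Vh, g)
        V_e = cfg.saccade_peak_velocity(A_e)
        Ts = self._saccade_duration(A_e)
        T_h = 2.0 * A_h / Vh if A_h > 0 else 0.0
        self.s, self.A, self.g = s, A, g
        self.A_e, self.V_e, self.Ts = A_e, V_e, Ts
        self.A_h, self.T_h, self.Vh = A_h, T_h, Vh
        self.head_start = max(-lead, 0.0)
        self.sacc_on = max(lead, 0.0)
        self.duration = max(self.head_start + T_h, self.sacc_on + Ts) + 1e-9
        # bookkeeping for truth
        self.dH_sacc = self._H_disp(self.sacc_on + Ts) - self._H_disp(self.sacc_on)
        self.gaze_amp_saccade = s * (A_e + self.dH_sacc)

    @property
    def required_E0(self) -> float:
        """Start posture that makes the saccade sweep the eye symmetrically
        through the orbit (from -A_e/2 to +A_e/2 eye-in-head), keeping it
        inside the oculomotor range and the scene-camera field of view."""
        dH_pre = float(self._H_disp(self.sacc_on))
        return self.s * (self.g * dH_pre - self.A_e / 2.0)

    def _saccade_duration(self, A_e: float) -> float:
        return 2.0 * A_e / self.cfg.saccade_peak_velocity(A_e)

    @staticmethod
    def _window_disp(A_h, T_h, lead, Ts):
        """Head displacement during the saccade window [lead, lead + Ts] of
        head-movement phase; _bell_frac clips, so a negative lead (eye
        leads) is handled transparently."""
        if T_h <= 0:
            return 0.0
        return A_h * (_bell_frac((lead + Ts) / T_h) - _bell_frac(lead / T_h))

    def _head_for_recentering(self, A_e, lead, Vh, g, n_iter=60):
        """Head amplitude from the re-centering condition: the post-saccadic
        VOR should bring the eye back to the orbit center, which requires
        A_h = dH_saccade + dH_pre + A_e / (2 g).  Fixed-point iteration."""
        A_h = A_e / (2.0 * g) + 1.0
        for _ in range(n_iter):
            T_h = 2.0 * A_h / Vh
            Ts = self._saccade_duration(A_e)
            dHs = self._window_disp(A_h, T_h, lead, Ts)
            dH_pre = A_h * _bell_frac(max(lead, 0.0) / T_h)
            new = dHs + dH_pre + A_e / (2.0 * g)
            if abs(new - A_h) < 1e-12:
                A_h = new
                break
            A_h = new
        return A_h

    def _solve_amplitudes(self, A, lead, Vh, g):
        """Jointly solve saccade and head amplitudes.

        Constraints: (i) the gaze displacement over the movement equals the
        requested amplitude, A = A_e + g*dH_saccade + (1-g)*A_h; (ii) the
        head keeps rotating after the saccade by just enough for the VOR to
        re-center the eye.  (ii) fixes A_h for a trial A_e; (i) is solved by
        bracketing on A_e.  The emergent saccade share decreases with
        amplitude (sublinear saccadic contribution) and the eye trajectory
        stays within +/- A_e/2 of the orbit center.
        """
        if Vh <= 0:
            raise ValueError("unreachable amplitude: head peak velocity is zero")
        cap = min(self.cfg.saccade_amplitude_cap, A - 1e-9)

        def residual(A_e):
            A_h = self._head_for_recentering(A_e, lead, Vh, g)
            T_h = 2.0 * A_h / Vh
            dHs = self._window_disp(A_h, T_h, lead, self._saccade_duration(A_e))
            return A_e + g * dHs + (1.0 - g) * A_h - A

        grid = np.linspace(max(0.15 * cap, 0.5), cap, 80)
        vals = np.array([residual(x) for x in grid])
        up = np.flatnonzero((vals[:-1] < 0) & (vals[1:] >= 0))
        if len(up):
            i = int(up[0])
            A_e = float(brentq(residual, grid[i], grid[i + 1], xtol=1e-12))
            return A_e, self._head_for_recentering(A_e, lead, Vh, g)
        if vals[-1] < 0:
            # even the capped saccade plus re-centering head cannot reach the
            # amplitude: pin the eye at the cap and grow the head instead
            A_e = cap
            return A_e, self._solve_head(A, A_e, self._saccade_duration(A_e),
                                         lead, Vh, g)
        # residual positive everywhere: tiny shift, eye does nearly all of it
        A_e = float(grid[0])
        return A_e, self._head_for_recentering(A_e, lead, Vh, g)

    def _solve_head(self, A, A_e, Ts, lead, Vh, g):
        """Head amplitude for a fixed saccade amplitude (piecewise share
        mode): A = A_e + g*dH_saccade + (1-g)*A_h.

        The closure residual rises and then falls with head amplitude (a
        larger, slower head bell overlaps the saccade window less), so there
        are generally two roots.  The larger root is preferred: the head
        keeps rotating after the saccade (the VOR phase), partially
        re-centering the eye.
        """
        if Vh <= 0:
            raise ValueError("unreachable amplitude: head peak velocity is zero")

        def closure(A_h):
            T_h = 2.0 * A_h / Vh
            return A_e + g * self._window_disp(A_h, T_h, lead, Ts) \
                + (1.0 - g) * A_h - A

        lo = max(A - A_e, 1e-6)
        grid = np.geomspace(lo, 60.0 * A, 800)
        vals = np.array([closure(x) for x in grid])
        down = np.flatnonzero((vals[:-1] >= 0) & (vals[1:] < 0))
        up = np.flatnonzero((vals[:-1] < 0) & (vals[1:] >= 0))
        if len(down):
            i = int(down[-1])
        elif len(up):
            i = int(up[0])
        elif vals[0] >= 0:
            return float(grid[0])
        else:
            raise ValueError(
                f"unreachable amplitude {A:.1f} deg: head cannot close the "
                "residual during the saccade interval"
            )
        return float(brentq(closure, grid[i], grid[i + 1], xtol=1e-12))

    def _H_disp(self, tau):
        """Unsigned head displacement (deg) at local time tau."""
        if self.T_h <= 0:
            return np.zeros_like(np.asarray(tau, dtype=float)) if np.ndim(tau) else 0.0
        return self.A_h * _bell_frac((np.asarray(tau, dtype=float) - self.head_start)
                                     / self.T_h)

    def H(self, tau):
        return self.H0 + self.s * self._H_disp(tau)

    def E(self, tau):
        tau = np.asarray(tau, dtype=float)
        h = self._H_disp(tau)
        on, off = self.sacc_on, self.sacc_on + self.Ts
        h_on = float(self._H_disp(on))
        h_off = float(self._H_disp(off))
        e = np.empty_like(tau)
        pre = tau < on
        mid = (tau >= on) & (tau <= off)
        post = tau > off
        e[pre] = self.E0 - self.g * self.s * h[pre]
        e_on = self.E0 - self.g * self.s * h_on
        e[mid] = e_on + self.s * self.A_e * _bell_frac((tau[mid] - on) / self.Ts)
        e_off = e_on + self.s * self.A_e
        e[post] = e_off - self.g * self.s * (h[post] - h_off)
        return e

    def peak_gaze_velocity(self) -> float:
        tt = np.linspace(self.sacc_on, self.sacc_on + self.Ts, 2001)
        dt = tt[1] - tt[0]
        G = self.E(tt) + self.H(tt)
        return float(np.abs(np.gradient(G, dt)).max())

    def truth_event(self, condition: str = "") -> dict:
        on = self.t0 + self.sacc_on
        off = on + self.Ts
        return {
            "saccade_onset": on,
            "saccade_offset": off,
            "gaze_amplitude": self.gaze_amp_saccade,
            "gaze_amplitude_total": self.amp,
            "saccade_amplitude": self.s * self.A_e,
            "head_amplitude": self.s * self.dH_sacc,
            "head_amplitude_total": self.s * self.A_h,
            "peak_eye_velocity": self.V_e,
            "peak_head_velocity": self.Vh if self.A_h > 0 else 0.0,
            "peak_gaze_velocity": self.peak_gaze_velocity(),
            "head_movement_start": self.t0 + self.head_start,
            "head_movement_end": self.t0 + self.head_start + self.T_h,
            "condition": condition,
        }


# --------------------------------------------------------------------------
# timeline

class Timeline:
    """Ordered list of contiguous segments, evaluable at arbitrary times."""

    def __init__(self):
        self.segments: list[_Segment] = []
        self.starts: list[float] = []

    def append(self, seg: _Segment):
        self.segments.append(seg)
        self.starts.append(seg.t0)

    @property
    def duration(self) -> float:
        last = self.segments[-1]
        return last.t0 + last.duration

    def _eval(self, times, attr):
        t = np.asarray(times, dtype=float)
        out = np.empty_like(t)
        starts = np.asarray(self.starts)
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0,
                      len(self.segments) - 1)
        for k in np.unique(idx):
            seg = self.segments[k]
            m = idx == k
            tau = np.clip(t[m] - seg.t0, 0.0, seg.duration)
            out[m] = getattr(seg, attr)(tau)
        return out

    def E(self, times):
        return self._eval(times, "E")

    def H(self, times):
        return self._eval(times, "H")


# --------------------------------------------------------------------------
# truth / session containers

@dataclass
class SimTruth:
    events: pd.DataFrame
    c_true: float
    sync_offset: float
    timeline: Timeline
    config: SimConfig

    def E(self, t):
        return self.timeline.E(t)

    def H(self, t):
        return self.timeline.H(t)

    def G(self, t):
        return self.timeline.E(t) + self.timeline.H(t) + 0.0

    def to_dict(self) -> dict:
        return {
            "c_true": self.c_true,
            "sync_offset": self.sync_offset,
            "config": asdict(self.config),
            "events": self.events.to_dict(orient="records"),
        }


@dataclass
class SimSession:
    eye: pd.DataFrame          # timestamp, x_px, y_px, valid (eye clock)
    marker: pd.DataFrame       # timestamp, x0..y3, valid (head clock)
    targets: pd.DataFrame      # target_id, azimuth_deg
    annotations: dict
    truth: SimTruth
    scene_camera: geometry.CameraModel
    ceiling_camera: geometry.CameraModel
    marker_model: geometry.MarkerModel


# --------------------------------------------------------------------------
# public generators

def simulate_gaze_shift(amplitude: float, config: SimConfig | None = None,
                        E0: float | None = None, H0: float = 0.0,
                        t0: float = 0.0) -> GazeShiftSegment:
    """A single ground-truth gaze shift starting from a comfortable
    eye-in-head posture (eye countered by half the saccade amplitude)."""
    cfg = config or SimConfig()
    seg = GazeShiftSegment(t0, 0.0, H0, amplitude, cfg)
    seg.E0 = seg.required_E0 if E0 is None else E0
    return seg


def simulate_oscillation(duration: float, frequency: float, amplitude: float,
                         config: SimConfig | None = None,
                         E0: float = 0.0, H0: float = 0.0,
                         t0: float = 0.0) -> OscillationSegment:
    """Head shake under fixation (the synchronization signature)."""
    cycles = max(1, int(round(duration * frequency)))
    return OscillationSegment(t0, E0, H0, amplitude, frequency, cycles)


class _SessionBuilder:
    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.tl = Timeline()
        self.t = 0.0
        self.E = 0.0
        self.H = 0.0
        self.events: list[dict] = []
        self.calibration_fixations: list[dict] = []
        self.oscillations: list[list[float]] = []
        self.conditions: list[dict] = []

    def _push(self, seg: _Segment):
        self.tl.append(seg)
        self.t = seg.t0 + seg.duration
        self.E = seg.end_E
        self.H = seg.end_H

    def hold(self, duration: float):
        self._push(HoldSegment(self.t, self.E, self.H, duration))

    def recenter(self, target_E: float):
        if abs(target_E - self.E) < 1e-9:
            self.hold(self.cfg.recenter_duration)
        else:
            self._push(RecenterSegment(self.t, self.E, self.H, target_E,
                                       self.cfg.recenter_duration))

    def oscillate(self):
        cfg = self.cfg
        seg = OscillationSegment(self.t, self.E, self.H,
                                 cfg.oscillation_amplitude,
                                 cfg.oscillation_frequency,
                                 cfg.oscillation_cycles)
        self.oscillations.append([self.t, self.t + seg.duration])
        self._push(seg)

    def shift_to(self, target_G: float, condition: str = "",
                 record_fixation_target: float | None = None):
        cfg = self.cfg
        amp = target_G - (self.E + self.H)
        if abs(amp) < 1e-6:
            self.hold(cfg.pre_shift_hold)
            return
        seg = GazeShiftSegment(0.0, 0.0, 0.0, amp, cfg)
        self.recenter(seg.required_E0)
        self.hold(cfg.pre_shift_hold)
        seg.t0, seg.E0, seg.H0 = self.t, self.E, self.H
        self.events.append(seg.truth_event(condition))
        self._push(seg)
        self.hold(cfg.post_shift_hold)
        if record_fixation_target is not None:
            # fixation spans from shift end through the post-hold; the next
            # recenter keeps gaze on target too, but the hold is plenty
            self.calibration_fixations.append({
                "t0": seg.t0 + seg.duration + 0.01,
                "t1": self.t - 0.01,
                "azimuth_deg": record_fixation_target,
            })


def simulate_session(config: SimConfig | None = None) -> SimSession:
    """Generate a full synthetic protocol run.

    Layout: corner fixation (head-orientation zero), calibration sweep over
    all wall targets right-to-left and back (23 fixations), then the
    separation conditions, each bracketed by head-oscillation episodes at the
    corner target, with the configured number of alternating shifts per
    condition.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    azimuths = sorted({math.copysign(sep / 2.0, side)
                       for sep in cfg.target_separations for side in (-1, 1)})
    targets = pd.DataFrame({
        "target_id": range(len(azimuths)),
        "azimuth_deg": azimuths,
    })

    b = _SessionBuilder(cfg)
    b.hold(2.0)  # corner fixation: zero for the head orientation
    corner_window = [0.2, 1.8]

    # calibration sweep: rightmost -> leftmost -> back (23 fixations)
    sweep = azimuths + azimuths[-2::-1]
    for az in sweep:
        b.shift_to(az, condition="calibration", record_fixation_target=az)

    # conditions, bracketed by oscillation episodes at the corner
    for sep in cfg.target_separations:
        b.shift_to(0.0, condition="transition")
        b.hold(0.4)
        b.oscillate()
        b.hold(0.4)
        label = f"{sep:g}"
        right, left = -sep / 2.0, sep / 2.0
        b.shift_to(right, condition="transition")
        t_cond0 = b.t
        side = left
        for _ in range(cfg.shifts_per_condition):
            b.shift_to(side, condition=label)
            side = left if side == right else right
        b.conditions.append({"label": label, "separation_deg": sep,
                             "t0": t_cond0, "t1": b.t})
    b.shift_to(0.0, condition="transition")
    b.hold(0.4)
    b.oscillate()
    b.hold(1.0)

    tl = b.tl
    T = tl.duration

    # ---- eye stream (wearable tracker clock) -----------------------------
    w_fast = cfg.eye_interval_weight_fast()
    mean_ms = 1000.0 / cfg.eye_effective_rate_hz
    n_est = int(T * 1000.0 / mean_ms * 1.05) + 100
    # exact mixture proportions (not iid draws) so the realized effective
    # frequency matches the configured one to well under 0.1 Hz
    fast = np.zeros(n_est, dtype=bool)
    fast[: int(round(w_fast * n_est))] = True
    rng.shuffle(fast)
    modes = np.where(fast, cfg.eye_interval_modes_ms[0], cfg.eye_interval_modes_ms[1])
    sds = np.where(fast, cfg.eye_interval_sds_ms[0], cfg.eye_interval_sds_ms[1])
    intervals = np.clip(rng.normal(modes, sds), 0.5, None) / 1000.0
    t_eye = np.concatenate([[0.0], np.cumsum(intervals)])
    t_eye = t_eye[t_eye <= T]

    E_true = tl.E(t_eye)
    az = (E_true - cfg.calibration_constant_true
          + rng.normal(0.0, cfg.eye_noise_sd, len(t_eye)))
    el = rng.normal(0.0, cfg.eye_noise_sd, len(t_eye))
    scene_cam = geometry.CameraModel.from_fov(1088, 1080, 82.0)
    x_px, y_px = angles_to_pixels(az, el, scene_cam)
    eye_df = pd.DataFrame({
        "timestamp": t_eye + cfg.sync_offset_true,
        "x_px": x_px,
        "y_px": y_px,
        "valid": np.ones(len(t_eye), dtype=int),
    })

    # ---- head stream (ceiling camera clock) ------------------------------
    n_head = int(math.floor(T * cfg.head_rate)) + 1
    t_head = np.arange(n_head) / cfg.head_rate
    H_true = tl.H(t_head)
    yaw_cam = (cfg.marker_mount_yaw + H_true
               + rng.normal(0.0, cfg.head_noise_sd, n_head))
    yr = np.radians(yaw_cam)
    cz, sz = np.cos(yr), np.sin(yr)
    R = np.zeros((n_head, 3, 3))
    R[:, 0, 0] = cz
    R[:, 0, 1] = -sz
    R[:, 1, 0] = sz
    R[:, 1, 1] = cz
    R[:, 2, 2] = 1.0
    tvec = np.tile(np.array([0.02, -0.01, cfg.marker_distance]), (n_head, 1))
    ceil_cam = geometry.CameraModel(1152, 986, 3333.0, (576.0, 493.0))
    marker = geometry.MarkerModel(cfg.marker_side)
    corners = geometry.project_marker_batch(R, tvec, marker, ceil_cam)
    marker_df = pd.DataFrame({"timestamp": t_head})
    for k in range(4):
        marker_df[f"x{k}"] = corners[:, k, 0]
        marker_df[f"y{k}"] = corners[:, k, 1]
    marker_df["valid"] = 1

    annotations = {
        "corner_window": corner_window,
        "calibration_fixations": b.calibration_fixations,
        "oscillations": b.oscillations,
        "conditions": b.conditions,
    }
    truth = SimTruth(
        events=pd.DataFrame(b.events),
        c_true=cfg.calibration_constant_true,
        sync_offset=cfg.sync_offset_true,
        timeline=tl,
        config=cfg,
    )
    return SimSession(eye_df, marker_df, targets, annotations, truth,
                      scene_cam, ceil_cam, marker)
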