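"""Synchronize, resample and combine the eye (E) and head (H) signals.

World-fixed gaze is G = E + H + c, where c is a single additive constant
fitted to known target directions during a calibration sweep.  Before the
sum, both streams are linearly resampled onto a common uniform grid (the
analysis rate, 200 Hz by default), and the clock offset between the two
recording devices is recovered from head-oscillation episodes during which
the participant fixates a stationary point (so eye velocity mirrors head
velocity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import SampledSignal

__all__ = [
    "GazeRecord",
    "CalibrationResult",
    "resample_to_rate",
    "synchronize",
    "fuse",
    "calibrate_constant",
]

DEFAULT_RATE_HZ = 200.0
MAX_INTERP_GAP_S = 0.050  # grid points farther than this from data are invalid


@dataclass
class GazeRecord:
    """Uniform-grid record of eye-in-head, head and gaze angles (degrees)
    and their velocities (degrees/second)."""

    time: np.ndarray
    E: np.ndarray
    H: np.ndarray
    G: np.ndarray
    dE: np.ndarray
    dH: np.ndarray
    dG: np.ndarray
    valid: np.ndarray
    rate: float
    c: float = 0.0

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    def __len__(self) -> int:
        return len(self.time)

    def with_constant(self, c: float) -> "GazeRecord":
        """Return a record with the calibration constant applied to G."""
        return GazeRecord(self.time, self.E, self.H, self.G - self.c + c,
                          self.dE, self.dH, self.dG, self.valid, self.rate, c)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time,
            "E_deg": self.E,
            "H_deg": self.H,
            "G_deg": self.G,
            "dE_dps": self.dE,
            "dH_dps": self.dH,
            "dG_dps": self.dG,
            "valid": self.valid.astype(int),
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GazeRecord":
        t = df["time"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("record needs at least 2 samples")
        dts = np.diff(t)
        rate = 1.0 / np.median(dts)
        return cls(
            time=t,
            E=df["E_deg"].to_numpy(dtype=float),
            H=df["H_deg"].to_numpy(dtype=float),
            G=df["G_deg"].to_numpy(dtype=float),
            dE=df["dE_dps"].to_numpy(dtype=float),
            dH=df["dH_dps"].to_numpy(dtype=float),
            dG=df["dG_dps"].to_numpy(dtype=float),
            valid=df["valid"].to_numpy(dtype=bool),
            rate=round(rate, 6),
        )


@dataclass
class CalibrationResult:
    c: float
    per_target_error: np.ndarray
    mean_absolute_error: float
    targets: np.ndarray


# --------------------------------------------------------------------------

def resample_to_rate(signal: SampledSignal, rate: float = DEFAULT_RATE_HZ,
                     max_gap: float = MAX_INTERP_GAP_S,
                     start: float | None = None,
                     stop: float | None = None) -> SampledSignal:
    """Linear interpolation of the valid samples onto a uniform grid.

    The grid spans the valid range of the signal (or [start, stop] clipped to
    it).  Grid points farther than ``max_gap`` from any valid sample are
    marked invalid rather than extrapolated.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    t = signal.timestamps[signal.valid]
    v = signal.values[signal.valid]
    if len(t) < 2:
        raise ValueError("resampling needs at least 2 valid samples")
    t0 = t[0] if start is None else max(start, t[0])
    t1 = t[-1] if stop is None else min(stop, t[-1])
    dt = 1.0 / rate
    n = int(np.floor((t1 - t0) / dt + 1e-9)) + 1
    grid = t0 + np.arange(n) * dt
    out = np.interp(grid, t, v)
    # distance to nearest valid input sample
    idx = np.searchsorted(t, grid)
    left = t[np.clip(idx - 1, 0, len(t) - 1)]
    right = t[np.clip(idx, 0, len(t) - 1)]
    dist = np.minimum(np.abs(grid - left), np.abs(right - grid))
    ok = dist <= max_gap
    out = np.where(ok, out, np.nan)
    return SampledSignal(grid, out, ok)


def _velocity(values: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(values, dt)


def synchronize(eye: SampledSignal, head: SampledSignal,
                search_window: float = 1.0,
                rate: float = DEFAULT_RATE_HZ,
                min_peak_correlation: float = 0.5) -> float:
    """Clock offset of the eye stream relative to the head stream, seconds.

    Both signals must cover a head-oscillation episode recorded while the
    participant fixates (eye velocity ~ -head velocity).  The offset is the
    lag maximizing the cross-correlation of the eye velocity with the negated
    head velocity, refined to sub-sample precision by parabolic interpolation
    of the correlation peak.  Subtract the returned offset from the eye
    timestamps to align the streams.
    """
    eu = resample_to_rate(eye, rate)
    dt = 1.0 / rate
    # trim the head segment so every lag in the search window overlaps it
    # fully; correlations are then true coefficients at every lag
    b0 = max(head.timestamps[0], eu.timestamps[0] + search_window)
    b1 = min(head.timestamps[-1], eu.timestamps[-1] - search_window)
    if b1 - b0 < 0.5:
        raise ValueError("signals too short for the requested search window")
    hu = resample_to_rate(head, rate, start=b0, stop=b1)
    a = _velocity(np.nan_to_num(eu.values, nan=0.0), dt)
    b = -_velocity(np.nan_to_num(hu.values, nan=0.0), dt)
    # identical zero-phase smoothing of both velocity traces: the shake is
    # slow (~1 Hz) while differentiation noise is broadband, so this costs no
    # timing information but triples the correlation SNR
    from scipy.ndimage import gaussian_filter1d
    a = gaussian_filter1d(a, sigma=3.0, mode="nearest")
    b = gaussian_filter1d(b, sigma=3.0, mode="nearest")
    if len(a) < len(b):
        raise ValueError("eye segment must cover the head segment plus the "
                         "search window")
    b = b - b.mean()
    # trim the reference segment to its outermost velocity zero-crossings:
    # a window cut at nonzero velocity adds odd boundary terms to the
    # correlation of oscillatory signals, which biases the parabola vertex
    zc = np.flatnonzero(np.diff(np.signbit(b)))
    hu_t0 = hu.timestamps[0]
    if len(zc) >= 2 and zc[-1] - zc[0] > 10:
        b = b[zc[0] + 1: zc[-1] + 1]
        hu_t0 += (zc[0] + 1) * dt
    eb = float(np.sum(b * b))
    if eb == 0:
        raise ValueError("no oscillation signature found: flat head signal")
    # valid-mode correlation with sliding-window normalization: each lag is a
    # true correlation coefficient over the overlapped stretch
    nb = len(b)
    num = np.correlate(a, b, mode="valid")
    cs = np.concatenate([[0.0], np.cumsum(a * a)])
    ea = cs[nb:] - cs[:-nb]
    with np.errstate(divide="ignore", invalid="ignore"):
        xcorr = num / np.sqrt(ea * eb)
    xcorr[~np.isfinite(xcorr)] = -np.inf
    shifts = np.arange(len(xcorr))
    base = eu.timestamps[0] - hu_t0
    offsets = base + shifts * dt
    in_win = np.abs(offsets) <= search_window
    if not np.any(in_win):
        raise ValueError("search window excludes all lags")
    cand = np.flatnonzero(in_win)
    m = cand[np.argmax(xcorr[cand])]
    peak = xcorr[m]
    if peak < min_peak_correlation:
        raise ValueError(
            f"no oscillation signature found: peak correlation {peak:.2f} < "
            f"{min_peak_correlation}"
        )
    # parabolic sub-sample refinement on the *unnormalized* correlation: the
    # sliding-energy normalization is only for peak picking and thresholding
    # (its flanks are skewed wherever the eye window slides over
    # non-oscillation content, which would bias the vertex)
    k = m
    if 1 <= m <= len(num) - 2 and num[m] < max(num[m - 1], num[m + 1]):
        k = m - 1 if num[m - 1] > num[m + 1] else m + 1
    if 0 < k < len(num) - 1:
        y0, y1, y2 = num[k - 1], num[k], num[k + 1]
        denom2 = y0 - 2 * y1 + y2
        frac = 0.0 if denom2 == 0 else 0.5 * (y0 - y2) / denom2
        frac = float(np.clip(frac, -0.5, 0.5))
    else:
        frac = 0.0
    return float(base + (k + frac) * dt)


def fuse(E: SampledSignal, H: SampledSignal, c: float = 0.0) -> GazeRecord:
    """Combine uniform-grid E and H into a gaze record: G = E + H + c.

    Velocities are central differences.  A sample is invalid if either input
    is invalid.
    """
    if len(E) != len(H) or not np.allclose(E.timestamps, H.timestamps, atol=1e-9):
        raise ValueError("E and H must share the same uniform time grid")
    t = E.timestamps
    if len(t) < 3:
        raise ValueError("record too short")
    dt = float(np.median(np.diff(t)))
    if not np.allclose(np.diff(t), dt, atol=1e-9):
        raise ValueError("grid is not uniform")
    valid = E.valid & H.valid
    Ev = E.values
    Hv = H.values
    G = Ev + Hv + c
    dE = _velocity(np.nan_to_num(Ev, nan=0.0), dt)
    dH = _velocity(np.nan_to_num(Hv, nan=0.0), dt)
    dG = _velocity(np.nan_to_num(G, nan=0.0), dt)
    return GazeRecord(t, Ev, Hv, G, dE, dH, dG, valid,
                      rate=round(1.0 / dt, 6), c=c)


def central_window(t0: float, t1: float, fraction: float = 0.5) -> tuple[float, float]:
    """Central ``fraction`` of [t0, t1] (robust fixation windowing)."""
    mid = 0.5 * (t0 + t1)
    half = 0.5 * fraction * (t1 - t0)
    return mid - half, mid + half


def calibrate_constant(G_raw: SampledSignal | GazeRecord,
                       fixation_windows, target_azimuths) -> CalibrationResult:
    """Least-squares additive constant from fixations of known targets.

    ``fixation_windows`` is a sequence of (t0, t1) in record time; windows
    and ``target_azimuths`` are parallel.  c minimizes
    sum((median(G in window) + c - target)^2); the closed form is the mean of
    (target - median window gaze).  The median makes each window robust to
    microsaccades and noise.
    """
    if isinstance(G_raw, GazeRecord):
        t, v, ok = G_raw.time, G_raw.G, G_raw.valid
    else:
        t, v, ok = G_raw.timestamps, G_raw.values, G_raw.valid
    targets = np.asarray(target_azimuths, dtype=float)
    windows = list(fixation_windows)
    if len(windows) != len(targets):
        raise ValueError("one target azimuth per fixation window required")
    if len(windows) == 0:
        raise ValueError("at least one fixation window required")
    if len(set(np.round(targets, 6))) < 2:
        import warnings
        warnings.warn("fewer than 2 distinct targets: c is estimable but "
                      "unvalidated", stacklevel=2)
    medians = np.empty(len(windows))
    for i, (t0, t1) in enumerate(windows):
        m = (t >= t0) & (t <= t1) & ok
        if not np.any(m):
            raise ValueError(f"no valid gaze samples in fixation window {i}")
        medians[i] = np.median(v[m])
    c = float(np.mean(targets - medians))
    residuals = medians + c - targets
    return CalibrationResult(
        c=c,
        per_target_error=np.abs(residuals),
        mean_absolute_error=float(np.mean(np.abs(residuals))),
        targets=targets,
    )
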