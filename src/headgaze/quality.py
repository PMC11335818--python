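"""Data-quality metrics: accuracy, windowed RMS-S2S precision, effective
frequency and the sample-interval distribution.

Precision follows the windowed sample-to-sample convention: the RMS of
successive differences is computed in every sliding window (default 41
samples, i.e. 205 ms at 200 Hz using the n x dt bookkeeping) and the median
across windows is reported.  The median makes the metric robust to windows
spanning saccades or blinks, so no fixation classification is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fusion import GazeRecord
from .signals import SampledSignal

__all__ = [
    "QualityReport",
    "accuracy",
    "rms_s2s_precision",
    "effective_frequency",
    "interval_distribution",
    "window_duration_ms",
    "quality_report",
]

DEFAULT_WINDOW_SAMPLES = 41


def window_duration_ms(window_samples: int, rate_hz: float) -> float:
    """Window duration bookkeeping, n x dt convention (41 @ 200 Hz -> 205 ms)."""
    return window_samples * 1000.0 / rate_hz


@dataclass
class QualityReport:
    mean_absolute_accuracy: float
    precision_rms_s2s: dict            # per signal name -> degrees
    effective_frequency: float         # Hz, raw eye stream
    interval_modes: list               # [(mode_ms, sd_ms), ...]
    window_samples: int = DEFAULT_WINDOW_SAMPLES
    window_ms: float = 205.0

    def to_dict(self) -> dict:
        return {
            "mean_absolute_accuracy_deg": self.mean_absolute_accuracy,
            "precision_rms_s2s_deg": {k: float(v) for k, v in self.precision_rms_s2s.items()},
            "effective_frequency_hz": self.effective_frequency,
            "interval_modes_ms": [[float(m), float(s)] for m, s in self.interval_modes],
            "precision_window_samples": self.window_samples,
            "precision_window_ms": self.window_ms,
        }


# --------------------------------------------------------------------------

def accuracy(record: GazeRecord, fixation_windows, target_azimuths) -> float:
    """Mean over fixation windows of |median(G in window) - target|, degrees."""
    targets = np.asarray(target_azimuths, dtype=float)
    windows = list(fixation_windows)
    if len(windows) == 0:
        raise ValueError("accuracy needs at least one fixation window")
    errs = []
    for (t0, t1), target in zip(windows, targets):
        m = (record.time >= t0) & (record.time <= t1) & record.valid
        if not np.any(m):
            continue
        errs.append(abs(float(np.median(record.G[m])) - target))
    if not errs:
        raise ValueError("no valid samples in any fixation window")
    return float(np.mean(errs))


def rms_s2s_precision(values, valid=None,
                      window_samples: int = DEFAULT_WINDOW_SAMPLES) -> float:
    """Median over sliding windows of the RMS sample-to-sample deviation.

    ``values`` must be uniformly sampled.  The window slides by one sample;
    windows containing any invalid sample are skipped.
    """
    v = np.asarray(values, dtype=float)
    if window_samples < 2:
        raise ValueError("window_samples must be >= 2")
    n = len(v)
    if n < window_samples:
        raise ValueError(f"signal ({n} samples) shorter than one window "
                         f"({window_samples} samples)")
    ok = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    d2 = np.diff(np.where(ok, v, 0.0)) ** 2
    w = window_samples - 1  # differences per window
    cs = np.concatenate([[0.0], np.cumsum(d2)])
    sums = cs[w:] - cs[:-w]                     # per window start
    rms = np.sqrt(sums / w)
    bad = np.concatenate([[0], np.cumsum(~ok)])
    nbad = bad[window_samples:] - bad[:-window_samples]
    keep = nbad == 0
    if not np.any(keep):
        raise ValueError("no window free of invalid samples")
    return float(np.median(rms[: len(keep)][keep]))


def effective_frequency(timestamps, valid=None) -> float:
    """Number of valid samples divided by the first-to-last time span, Hz."""
    t = np.asarray(timestamps, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("zero-duration recording")
    n_valid = len(t) if valid is None else int(np.count_nonzero(valid))
    return float(n_valid / span)


def interval_distribution(timestamps, max_modes: int = 2) -> list[tuple[float, float]]:
    """Cluster successive sample intervals into up to two modes.

    Returns [(mean_ms, sd_ms), ...] sorted by mode.  Uses 1-D two-means with
    a separation criterion as the unimodality fallback: if the cluster means
    are closer than 4x the larger within-cluster spread, a single mode is
    reported.
    """
    t = np.asarray(timestamps, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 samples")
    d = np.diff(t) * 1000.0  # ms
    if max_modes == 1 or np.ptp(d) < 1e-9:
        return [(float(d.mean()), float(d.std()))]
    # Lloyd's algorithm, k = 2, deterministic init at the extremes
    c = np.array([d.min(), d.max()], dtype=float)
    labels = np.zeros(len(d), dtype=int)
    for _ in range(100):
        labels = (np.abs(d[:, None] - c[None, :])).argmin(axis=1)
        if len(np.unique(labels)) < 2:
            break
        new_c = np.array([d[labels == k].mean() for k in (0, 1)])
        if np.allclose(new_c, c):
            c = new_c
            break
        c = new_c
    if len(np.unique(labels)) < 2:
        return [(float(d.mean()), float(d.std()))]
    modes = []
    spreads = []
    for k in (0, 1):
        dk = d[labels == k]
        modes.append((float(dk.mean()), float(dk.std())))
        spreads.append(float(dk.std()))
    sep = abs(modes[0][0] - modes[1][0])
    if sep < 4.0 * max(max(spreads), 1e-12):
        return [(float(d.mean()), float(d.std()))]
    return sorted(modes)


def quality_report(record: GazeRecord, fixation_windows, target_azimuths,
                   raw_eye_timestamps, raw_eye_valid=None,
                   window_samples: int = DEFAULT_WINDOW_SAMPLES) -> QualityReport:
    """Assemble the full quality report for a processed recording."""
    prec = {
        "E": rms_s2s_precision(record.E, record.valid, window_samples),
        "H": rms_s2s_precision(record.H, record.valid, window_samples),
        "G": rms_s2s_precision(record.G, record.valid, window_samples),
    }
    return QualityReport(
        mean_absolute_accuracy=accuracy(record, fixation_windows, target_azimuths),
        precision_rms_s2s=prec,
        effective_frequency=effective_frequency(raw_eye_timestamps, raw_eye_valid),
        interval_modes=interval_distribution(raw_eye_timestamps),
        window_samples=window_samples,
        window_ms=window_duration_ms(window_samples, record.rate),
    )
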