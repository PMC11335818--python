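"""Figure helpers: signal anatomy, relative-timing scatter, main-sequence
panels.  Matplotlib is imported lazily so headless pipelines never pay for it."""

from __future__ import annotations

import numpy as np

from .events import GazeShiftEvent, analysis_epoch, events_to_dataframe
from .fusion import GazeRecord


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_shift_anatomy(record: GazeRecord, event: GazeShiftEvent, path=None):
    """One gaze shift: E/H/G positions (top) and velocities (bottom), with
    saccade start/end and head-movement end marked."""
    plt = _plt()
    ep = analysis_epoch(record, event)
    t = ep.time - event.saccade_onset
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for ax, trio, unit in ((ax0, (ep.E, ep.H, ep.G), "deg"),
                           (ax1, (ep.dE, ep.dH, ep.dG), "deg/s")):
        for y, color, label in zip(trio, ("tab:red", "tab:blue", "black"),
                                   ("eye-in-head", "head", "gaze")):
            ax.plot(t, y, color=color, label=label)
        ax.set_ylabel(unit)
    for x, color in ((0.0, "purple"),
                     (event.saccade_offset - event.saccade_onset, "gray"),
                     (event.head_movement_end - event.saccade_onset, "gold")):
        ax0.axvline(x, color=color, ls="--", lw=0.8)
        ax1.axvline(x, color=color, ls="--", lw=0.8)
    ax0.legend(loc="best", fontsize=8)
    ax1.set_xlabel("time from saccade onset (s)")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_relative_timing(events: list[GazeShiftEvent], path=None):
    """Pre-saccade eye vs head velocity (VOR line) and post- vs pre-saccade
    head velocity (head-lead signature)."""
    plt = _plt()
    df = events_to_dataframe([e for e in events if e.timing_valid])
    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(9, 4))
    ax0.scatter(df["pre_head_vel"], df["pre_eye_vel"], s=10, alpha=0.6)
    lim = np.nanmax(np.abs(df[["pre_head_vel", "pre_eye_vel"]].to_numpy())) * 1.1
    ax0.plot([-lim, lim], [lim, -lim], "k--", lw=0.8)
    ax0.set_xlabel("pre head vel (deg/s)")
    ax0.set_ylabel("pre eye vel (deg/s)")
    ax1.scatter(df["pre_head_vel"], df["post_head_vel"], s=10, alpha=0.6)
    lim = np.nanmax(np.abs(df[["pre_head_vel", "post_head_vel"]].to_numpy())) * 1.1
    ax1.plot([-lim, lim], [-lim, lim], "k--", lw=0.8)
    ax1.set_xlabel("pre head vel (deg/s)")
    ax1.set_ylabel("post head vel (deg/s)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_main_sequence(summary, path=None):
    """Per-condition amplitude/velocity/duration panels."""
    plt = _plt()
    agg = summary.per_condition
    x = agg["gaze_amplitude_mean"]
    panels = [
        ("saccade_amplitude_mean", "saccade amplitude (deg)"),
        ("peak_saccade_velocity_mean", "peak saccade velocity (deg/s)"),
        ("saccade_duration_mean", "saccade duration (s)"),
        ("peak_head_velocity_mean", "peak head velocity (deg/s)"),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (col, label) in zip(axes.ravel(), panels):
        sem_col = col.replace("_mean", "_sem")
        ax.errorbar(x, agg[col], yerr=agg[sem_col],
                    xerr=agg["gaze_amplitude_sem"], fmt="o-")
        ax.set_xlabel("gaze amplitude (deg)")
        ax.set_ylabel(label)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
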