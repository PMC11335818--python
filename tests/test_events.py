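import numpy as np
import pytest

from headgaze import events as ev
from headgaze import fusion
from headgaze.signals import SampledSignal
from headgaze.simulate import (SimConfig, Timeline, HoldSegment,
                               simulate_gaze_shift, simulate_oscillation)
from conftest import matched_events


def record_from_segments(*segs, pad=1.0, rate=200.0, noise=0.0, seed=0):
    """Noise-free (or noisy) uniform record from simulator segments laid out
    back to back with stationary padding."""
    tl = Timeline()
    t = 0.0
    E0 = segs[0].E0
    H0 = segs[0].H0
    tl.append(HoldSegment(t, E0, H0, pad))
    t += pad
    for seg in segs:
        seg.t0 = t
        tl.append(seg)
        t += seg.duration
        tl.append(HoldSegment(t, seg.end_E, seg.end_H, pad))
        t += pad
    grid = np.arange(0.0, t, 1.0 / rate)
    rng = np.random.default_rng(seed)
    E = tl.E(grid) + rng.normal(0, noise, len(grid))
    H = tl.H(grid) + rng.normal(0, noise, len(grid))
    rec = fusion.fuse(SampledSignal(grid, E), SampledSignal(grid, H), c=0.0)
    return rec, tl


def single_shift_record(amplitude=90.0, cfg=None, **kw):
    cfg = cfg or SimConfig()
    seg = simulate_gaze_shift(amplitude, cfg)
    rec, _ = record_from_segments(seg, **kw)
    return rec, seg


# --------------------------------------------------------------------------
# detection

def test_single_90deg_shift_detected_within_one_sample():
    rec, seg = single_shift_record(90.0)
    evs = ev.detect_gaze_saccades(rec)
    assert len(evs) == 1
    e = evs[0]
    true_on = 1.0 + seg.sacc_on
    true_off = true_on + seg.Ts
    assert abs(e.saccade_onset - true_on) <= rec.dt + 1e-9
    assert abs(e.saccade_offset - true_off) <= rec.dt + 1e-9
    assert e.gaze_amplitude == pytest.approx(90.0, abs=0.3)


def test_constant_gaze_vor_oscillation_yields_no_events():
    osc = simulate_oscillation(5.0, 1.0, 10.0)
    rec, _ = record_from_segments(osc)
    assert ev.detect_gaze_saccades(rec) == []


def test_small_events_discarded():
    rec, _ = single_shift_record(90.0)
    evs = ev.detect_gaze_saccades(rec, min_amplitude=95.0)
    assert evs == []


def test_detection_requires_velocities():
    rec, _ = single_shift_record(20.0)
    rec.dG = None
    with pytest.raises(ValueError):
        ev.detect_gaze_saccades(rec)


def test_detection_amplitude_monotone():
    amps = [10.0, 20.0, 40.0, 80.0, 120.0]
    measured = []
    for a in amps:
        rec, _ = single_shift_record(a)
        evs = ev.detect_gaze_saccades(rec)
        assert len(evs) == 1
        measured.append(abs(evs[0].gaze_amplitude))
    assert np.all(np.diff(measured) > 0)


def test_session_event_count_and_amplitudes(full_session, full_processed):
    tr, det = matched_events(full_session.truth.events, full_processed.events)
    amperr = [abs(abs(d.gaze_amplitude) - abs(g))
              for d, g in zip(det, tr.gaze_amplitude)]
    assert max(amperr) < 0.5
    labels = [e.condition for e in det]
    for sep in full_session.truth.config.target_separations:
        assert labels.count(f"{sep:g}") == full_session.truth.config.shifts_per_condition


def test_event_decomposition_consistency(full_processed):
    for e in full_processed.events:
        assert abs(e.gaze_amplitude - e.saccade_amplitude - e.head_amplitude) < 1.0


def test_vor_gaze_stability(full_processed):
    # during gain-1 VOR intervals the measured gaze is far quieter than the
    # head (the true gaze velocity is exactly zero; the measured residual is
    # noise plus resampling jitter of the fast eye/head traces)
    rec = full_processed.record
    dG = ev.smoothed_velocity(rec.G, rec.dt)
    dH = ev.smoothed_velocity(rec.H, rec.dt)
    saw_fast_head = False
    for e in full_processed.events:
        if not np.isfinite(e.vor_start):
            continue
        m = (rec.time >= e.vor_start + 0.03) & (rec.time <= e.vor_end - 0.03)
        if not m.any():
            continue
        gaze_q = np.median(np.abs(dG[m]))
        assert gaze_q < 10.0
        if np.abs(dH[m]).max() > 100.0:
            saw_fast_head = True
            assert gaze_q < np.abs(dH[m]).max() / 10.0
    assert saw_fast_head


# --------------------------------------------------------------------------
# VOR phase

def test_vor_gain_recovery_gain_1():
    rec, seg = single_shift_record(120.0)
    e = ev.detect_gaze_saccades(rec)[0]
    assert np.isfinite(e.vor_gain)
    assert e.vor_gain == pytest.approx(1.0, abs=0.02)


def test_vor_gain_recovery_gain_09():
    cfg = SimConfig(vor_gain=0.9)
    rec, seg = single_shift_record(120.0, cfg)
    e = ev.detect_gaze_saccades(rec)[0]
    assert e.vor_gain == pytest.approx(0.9, abs=0.02)


def test_vor_empty_when_head_stops_at_offset():
    # hand-built record: saccade with stationary head -> no VOR phase
    t = np.arange(0, 2, 0.005)
    E = np.where(t < 1.0, 0.0, 30.0)
    ramp = (t >= 0.9) & (t < 1.0)
    E[ramp] = (t[ramp] - 0.9) * 300.0
    rec = fusion.fuse(SampledSignal(t, E), SampledSignal(t, np.zeros_like(t)), c=0.0)
    evs = ev.detect_gaze_saccades(rec)
    assert len(evs) == 1
    assert not np.isfinite(evs[0].vor_gain)


def test_session_vor_gain(full_processed):
    gains = [e.vor_gain for e in full_processed.events if np.isfinite(e.vor_gain)]
    assert len(gains) > 100
    assert np.mean(gains) == pytest.approx(1.0, abs=0.02)


# --------------------------------------------------------------------------
# pre/post velocities and head lead

def test_head_lead_vor_line(full_processed):
    # Fig. 4C pattern: pre-onset eye and head velocities on the -45 deg line
    pre_e = np.array([e.pre_eye_vel for e in full_processed.events if e.timing_valid])
    pre_h = np.array([e.pre_head_vel for e in full_processed.events if e.timing_valid])
    big = np.abs(pre_h) > 10.0
    assert big.sum() > 50
    np.testing.assert_allclose(pre_e[big], -pre_h[big], rtol=0.2, atol=3.0)


def test_head_lead_post_exceeds_pre(full_processed):
    # Fig. 4D pattern: same sign, much faster after onset
    for e in full_processed.events:
        if not e.timing_valid:
            continue
        assert np.sign(e.post_head_vel) == np.sign(e.pre_head_vel)
        assert abs(e.post_head_vel) > abs(e.pre_head_vel)


def test_eye_lead_configuration_head_still_before_onset():
    cfg = SimConfig(head_lead=-0.08)
    rec, seg = single_shift_record(60.0, cfg)
    e = ev.detect_gaze_saccades(rec)[0]
    assert e.timing_valid
    assert abs(e.pre_head_vel) < 5.0
    assert not e.head_lead


def test_classify_head_lead_trivial():
    e = ev.GazeShiftEvent(0, 0.1, 20, 15, 5, 0, 0, 0, 0.1, 0, 0, 0,
                          pre_head_vel=20.0, post_head_vel=120.0,
                          pre_eye_vel=-20.0, post_eye_vel=100.0,
                          timing_valid=True)
    assert ev.classify_head_lead(e)
    e.pre_head_vel = 0.5
    assert not ev.classify_head_lead(e)
    e.pre_head_vel, e.post_head_vel = 20.0, -120.0
    assert not ev.classify_head_lead(e)


def test_session_head_lead_fraction(full_processed):
    assert full_processed.summary.head_leads_fraction == 1.0


def test_insufficient_context_flagged():
    cfg = SimConfig(head_lead=0.01)
    seg = simulate_gaze_shift(30.0, cfg)
    rec, _ = record_from_segments(seg, pad=0.05)  # almost no context
    evs = ev.detect_gaze_saccades(rec)
    assert len(evs) == 1
    assert not evs[0].timing_valid


# --------------------------------------------------------------------------
# coordination summary

def test_summary_slope_recovery(full_processed, full_session):
    cfg = full_session.truth.config
    assert full_processed.summary.head_velocity_slope == pytest.approx(
        cfg.head_velocity_slope, abs=0.1)


def test_summary_identical_events_zero_sem():
    base = dict(saccade_onset=0.0, saccade_offset=0.1, gaze_amplitude=30.0,
                saccade_amplitude=25.0, head_amplitude=5.0,
                peak_gaze_velocity=400.0, peak_eye_velocity=380.0,
                peak_head_velocity=60.0, saccade_duration=0.1,
                head_movement_start=-0.1, head_movement_end=0.4,
                head_movement_duration=0.5, timing_valid=True)
    evs = ([ev.GazeShiftEvent(**base, condition="a") for _ in range(5)]
           + [ev.GazeShiftEvent(**{**base, "gaze_amplitude": 60.0,
                                   "peak_head_velocity": 120.0},
                                condition="b") for _ in range(5)])
    s = ev.coordination_summary(evs)
    assert np.allclose(s.per_condition["gaze_amplitude_sem"], 0.0)
    assert s.head_velocity_slope == pytest.approx(2.0)


def test_summary_sublinearity_flag(full_processed):
    s = full_processed.summary
    assert s.saccade_sublinear
    ratio = (s.per_condition["saccade_amplitude_mean"]
             / s.per_condition["gaze_amplitude_mean"]).to_numpy()
    assert np.all(np.diff(ratio) < 0)


def test_summary_configured_piecewise_sublinearity():
    # generator configured with an explicit saturating rule still flags it
    cfg = SimConfig(eye_share_mode="piecewise", eye_share_break=40.0,
                    eye_share_full=1.0, eye_share_beyond=0.45)
    evs = []
    for cond, amp in (("a", 20.0), ("b", 60.0)):
        for k in range(3):
            seg = simulate_gaze_shift(amp, cfg)
            rec, _ = record_from_segments(seg)
            e = ev.detect_gaze_saccades(rec)[0]
            e.condition = cond
            evs.append(e)
    s = ev.coordination_summary(evs)
    assert s.saccade_sublinear


def test_summary_too_few_events_errors():
    e = ev.GazeShiftEvent(0, 0.1, 30, 25, 5, 0, 0, 0, 0.1, 0, 0, 0,
                          condition="only")
    with pytest.raises(ValueError, match="too few"):
        ev.coordination_summary([e])


# --------------------------------------------------------------------------
# epochs / dataframe

def test_analysis_epoch_span(full_processed):
    e = next(x for x in full_processed.events if x.timing_valid)
    epoch = ev.analysis_epoch(full_processed.record, e)
    assert epoch.time[0] >= e.saccade_onset - 0.2505
    assert epoch.time[-1] <= e.saccade_onset + 0.7505
    assert len(epoch) > 150


def test_events_dataframe_columns(full_processed):
    df = ev.events_to_dataframe(full_processed.events)
    for col in ("saccade_onset", "gaze_amplitude", "vor_gain", "condition",
                "pre_head_vel", "post_head_vel", "head_lead"):
        assert col in df.columns
    assert len(df) == len(full_processed.events)
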