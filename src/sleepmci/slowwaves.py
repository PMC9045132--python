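"""Four-step slow-wave detector and per-segment slow-wave features.

Steps, all on the 0.3-2 Hz FIR-filtered trace:

I.   bandpass 0.3-2 Hz (transition band 0.2 Hz);
II.  find candidate troughs with amplitude in [-300, -40] uV and candidate
     positive peaks in [10, 150] uV (minimum peak separation 0.2 s);
III. pair each trough with the nearest subsequent positive peak and measure
     peak-to-peak amplitude, phase durations from the bracketing zero
     crossings, and the trough-to-midline slope;
IV.  keep events with PTP in [75, 400] uV, negative-phase duration
     0.3-1.5 s, positive-phase duration 0.1-1 s and positive slope.

Overlapping events are resolved by keeping the larger-PTP one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class SlowWaveParams:
    band: tuple[float, float] = (0.3, 2.0)
    transition_hz: float = 0.2
    neg_peak_range: tuple[float, float] = (-300.0, -40.0)
    pos_peak_range: tuple[float, float] = (10.0, 150.0)
    ptp_range: tuple[float, float] = (75.0, 400.0)
    neg_dur_range: tuple[float, float] = (0.3, 1.5)
    pos_dur_range: tuple[float, float] = (0.1, 1.0)
    min_peak_separation_s: float = 0.2


@dataclass
class SlowWaveEvent:
    start: float
    end: float
    duration: float
    val_neg_peak: float   # uV, negative
    val_pos_peak: float   # uV, positive
    ptp: float            # uV
    slope: float          # uV/s, trough to midline
    frequency: float      # Hz, 1/duration
    neg_phase_dur: float  # s
    pos_phase_dur: float  # s

FEATURE_NAMES = ["sw_density", "sw_duration", "sw_val_neg_peak",
                 "sw_val_pos_peak", "sw_ptp", "sw_slope", "sw_frequency"]


def sw_filter(x, sampling_rate, params: SlowWaveParams | None = None):
    """Step I: 0.3-2 Hz zero-phase FIR with the stated 0.2 Hz transition."""
    params = params or SlowWaveParams()
    numtaps = int(np.ceil(3.3 * sampling_rate / params.transition_hz)) | 1
    max_taps = max(3, (np.asarray(x).size - 1) // 3)
    if numtaps > max_taps:
        numtaps = max_taps if max_taps % 2 == 1 else max_taps - 1
    taps = sps.firwin(numtaps, list(params.band), pass_zero=False,
                      window="hamming", fs=sampling_rate)
    return sps.filtfilt(taps, [1.0], np.asarray(x, dtype=float))


def detect_slow_waves(segment, sampling_rate,
                      params: SlowWaveParams | None = None) -> list[SlowWaveEvent]:
    params = params or SlowWaveParams()
    fs = sampling_rate
    x = np.asarray(segment, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("segment must be at least 2 s long")
    z = sw_filter(x, fs, params)

    dist = int(round(params.min_peak_separation_s * fs))
    neg_lo, neg_hi = params.neg_peak_range
    pos_lo, pos_hi = params.pos_peak_range
    troughs, _ = sps.find_peaks(-z, height=(-neg_hi, -neg_lo), distance=dist)
    peaks, _ = sps.find_peaks(z, height=(pos_lo, pos_hi), distance=dist)
    if troughs.size == 0 or peaks.size == 0:
        return []

    # zero crossings of the filtered trace
    down = np.flatnonzero((z[:-1] >= 0) & (z[1:] < 0))   # into negative phase
    up = np.flatnonzero((z[:-1] < 0) & (z[1:] >= 0))     # out of negative phase

    events = []
    for tr in troughs:
        nxt = peaks[peaks > tr]
        if nxt.size == 0:
            continue
        pk = nxt[0]
        # bracketing zero crossings of the negative phase
        d_before = down[down <= tr]
        u_after = up[up >= tr]
        if d_before.size == 0 or u_after.size == 0:
            continue
        d0, u0 = d_before[-1], u_after[0]
        # positive phase: from u0 to the next down crossing; the paired peak
        # must lie inside it
        d_after = down[down > u0]
        if d_after.size == 0:
            continue
        d1 = d_after[0]
        if not (u0 < pk < d1):
            continue
        neg_dur = (u0 - d0) / fs
        pos_dur = (d1 - u0) / fs
        val_neg = float(z[tr])
        val_pos = float(z[pk])
        ptp = val_pos - val_neg
        slope = abs(val_neg) / ((u0 - tr) / fs) if u0 > tr else 0.0
        # Step IV logical thresholds
        if not (params.ptp_range[0] <= ptp <= params.ptp_range[1]):
            continue
        if not (params.neg_dur_range[0] <= neg_dur <= params.neg_dur_range[1]):
            continue
        if not (params.pos_dur_range[0] <= pos_dur <= params.pos_dur_range[1]):
            continue
        if slope <= 0:
            continue
        duration = neg_dur + pos_dur
        events.append(SlowWaveEvent(
            start=d0 / fs, end=d1 / fs, duration=duration,
            val_neg_peak=val_neg, val_pos_peak=val_pos, ptp=ptp, slope=slope,
            frequency=1.0 / duration, neg_phase_dur=neg_dur,
            pos_phase_dur=pos_dur))

    # sort and drop overlaps, keeping the larger-PTP event
    events.sort(key=lambda e: e.start)
    kept: list[SlowWaveEvent] = []
    for e in events:
        if kept and e.start < kept[-1].end:
            if e.ptp > kept[-1].ptp:
                kept[-1] = e
            continue
        kept.append(e)
    return kept


def slow_wave_features(events, segment_duration: float) -> np.ndarray:
    """7 features: density (events/min) + means of the 6 event measures.

    Zeros when no events (same dense-matrix convention as the spindle
    features).
    """
    if segment_duration <= 0:
        raise ValueError("segment_duration must be positive")
    if not events:
        return np.zeros(7)
    density = len(events) / (segment_duration / 60.0)
    cols = np.array([[e.duration, e.val_neg_peak, e.val_pos_peak, e.ptp,
                      e.slope, e.frequency] for e in events])
    return np.r_[density, cols.mean(axis=0)]
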