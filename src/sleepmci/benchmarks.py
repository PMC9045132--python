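"""Seeded detector-characterization procedures.

These build synthetic probe signals, run the detectors, and summarize the
outcome. They are shared by the test suite and the acceptance script so
both exercise exactly the same computation.
"""

from __future__ import annotations

import numpy as np

from .slowwaves import detect_slow_waves
from .spindles import detect_spindles
from .synth import colored_noise, slow_wave_shape, synth_spindle


def slow_wave_ptp_sweep(seed: int, n_waves: int = 25,
                        ptp_range: tuple[float, float] = (20.0, 500.0),
                        neg_dur: float = 0.6, pos_dur: float = 0.4,
                        sampling_rate: float = 100.0,
                        noise_rms: float = 2.0):
    """Inject waves with evenly spaced trough-to-peak amplitudes into
    low-amplitude 1/f background and run the slow-wave detector.

    Returns (injected_ptps, events)."""
    fs = sampling_rate
    spacing = 12.0
    n = int((n_waves + 1) * spacing * fs)
    x = colored_noise(n, 1.0, noise_rms, seed)
    ptps = np.linspace(*ptp_range, n_waves)
    for k, ptp in enumerate(ptps):
        wave = slow_wave_shape(float(ptp), neg_dur, pos_dur, fs)
        i0 = int((k + 0.5) * spacing * fs)
        x[i0:i0 + wave.size] += wave
    return ptps, detect_slow_waves(x, fs)


def slow_wave_negdur_sweep(seed: int, n_waves: int = 20,
                           negdur_range: tuple[float, float] = (0.1, 2.0),
                           ptp: float = 150.0, pos_dur: float = 0.4,
                           sampling_rate: float = 100.0,
                           noise_rms: float = 2.0):
    """Sweep the negative-phase duration at fixed valid amplitude.

    Returns (injected_neg_durs, events)."""
    fs = sampling_rate
    spacing = 12.0
    n = int((n_waves + 1) * spacing * fs)
    x = colored_noise(n, 1.0, noise_rms, seed)
    durs = np.linspace(*negdur_range, n_waves)
    for k, neg in enumerate(durs):
        wave = slow_wave_shape(ptp, float(neg), pos_dur, fs)
        i0 = int((k + 0.5) * spacing * fs)
        x[i0:i0 + wave.size] += wave
    return durs, detect_slow_waves(x, fs)


def spindle_recovery(seeds=(100, 101, 102, 103, 104), n_per_segment: int = 6,
                     amp_over_rms: float = 2.5, noise_rms: float = 10.0,
                     sampling_rate: float = 100.0):
    """Recall/precision of the spindle detector on injected 13 Hz, 1-s
    bursts at ``amp_over_rms`` times the background RMS.

    A truth event counts as recovered when a detection overlaps at least
    half of it; a detection counts as matched when it touches any truth
    event. Returns dict with recall, precision and counts."""
    fs = sampling_rate
    n_truth = n_hit = n_det = n_matched = 0
    for seed in seeds:
        x = colored_noise(int(300 * fs), 1.0, noise_rms, seed)
        truth = []
        for k in range(n_per_segment):
            t0 = 30.0 + 45.0 * k
            burst = synth_spindle(13.0, 1.0, amp_over_rms * noise_rms, fs)
            i0 = int(t0 * fs)
            x[i0:i0 + burst.size] += burst
            truth.append((t0, t0 + 1.0))
        events = detect_spindles(x, fs)
        n_det += len(events)
        for lo, hi in truth:
            n_truth += 1
            if any(min(hi, e.end) - max(lo, e.start) >= 0.5 * (hi - lo)
                   for e in events):
                n_hit += 1
        for e in events:
            if any(min(hi, e.end) - max(lo, e.start) > 0 for lo, hi in truth):
                n_matched += 1
    return {"recall": n_hit / n_truth, "precision": n_matched / n_det,
            "n_truth": n_truth, "n_detected": n_det}


def spindle_density_curve(seed: int, injected_counts=(2, 6, 12),
                          noise_rms: float = 10.0,
                          sampling_rate: float = 100.0):
    """Detected spindle count as a function of injected count on
    otherwise identical background."""
    fs = sampling_rate
    detected = []
    for n_inj in injected_counts:
        x = colored_noise(int(300 * fs), 1.0, noise_rms, seed)
        for k in range(n_inj):
            t0 = 12.0 + (276.0 / max(n_inj, 1)) * k
            burst = synth_spindle(13.0, 1.0, 2.5 * noise_rms, fs)
            i0 = int(t0 * fs)
            x[i0:i0 + burst.size] += burst
        detected.append(len(detect_spindles(x, fs)))
    return list(injected_counts), detected
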