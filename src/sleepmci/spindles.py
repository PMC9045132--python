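"""Three-threshold sleep-spindle detector and per-segment spindle features.

The detector works on two filtered copies of the segment: a broadband
(1-30 Hz) and a sigma-band (12-15 Hz) trace. Three time-resolved criteria
are computed:

1. relative sigma power from a short-time Fourier transform (2-s windows,
   200-ms hop), thresholded at 0.2;
2. the moving Pearson correlation between the broadband and sigma traces
   (300-ms windows, 100-ms step), thresholded at 0.65;
3. the moving RMS of the sigma trace (same windows), thresholded at
   mean + 1.5 x SD of the RMS series.

A per-sample decision count (0-3) is smoothed with a 100-ms moving
average; spans where the smoothed count reaches 2 of 3 seed events, whose
boundaries extend over the surrounding samples where >= 2 raw criteria
hold. Events closer than 500 ms are merged and events outside the
0.5-2 s duration bounds are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert

from .preprocess import bandpass_fir


@dataclass
class SpindleParams:
    broad_band: tuple[float, float] = (1.0, 30.0)
    sigma_band: tuple[float, float] = (12.0, 15.0)
    stft_window_s: float = 2.0
    stft_hop_s: float = 0.2
    corr_window_s: float = 0.3
    corr_step_s: float = 0.1
    rel_pow_thresh: float = 0.2
    corr_thresh: float = 0.65
    rms_sd_factor: float = 1.5
    filter_transition_hz: float = 1.5
    smooth_s: float = 0.1
    merge_gap_s: float = 0.5
    min_dur_s: float = 0.5
    max_dur_s: float = 2.0


@dataclass
class SpindleEvent:
    start: float
    end: float
    duration: float
    amplitude: float     # peak-to-peak of the sigma-filtered trace, uV
    rms: float           # uV
    abspower: float      # log10(uV^2)
    relpower: float      # mean relative sigma power in the event
    frequency: float     # Hz, mean instantaneous frequency
    oscillations: int    # sigma-trace negative-to-positive zero crossings

FEATURE_NAMES = ["sp_density", "sp_duration", "sp_amplitude", "sp_rms",
                 "sp_abspower", "sp_relpower", "sp_frequency",
                 "sp_oscillations"]


@dataclass
class ThresholdSignals:
    """The three criterion series interpolated to the segment's sample grid."""

    rel_pow: np.ndarray
    mcorr: np.ndarray
    mrms: np.ndarray
    rms_thresh: float


def _moving_frames(x, win_n, step_n):
    """Strided frames (n_frames, win_n) and their center sample indices."""
    frames = sliding_window_view(x, win_n)[::step_n]
    centers = np.arange(frames.shape[0]) * step_n + win_n // 2
    return frames, centers


def _to_sample_grid(values, centers, n):
    """Linear interpolation with edge hold onto 0..n-1."""
    return np.interp(np.arange(n), centers, values)


def compute_threshold_signals(segment, sampling_rate,
                              params: SpindleParams | None = None,
                              _filtered=None) -> ThresholdSignals:
    """The three spindle criteria at sample resolution plus the RMS threshold."""
    params = params or SpindleParams()
    x = np.asarray(segment, dtype=float)
    fs = sampling_rate
    n = x.size
    win_stft = int(round(params.stft_window_s * fs))
    if n < win_stft:
        raise ValueError("segment shorter than one STFT window")

    if _filtered is None:
        broad = bandpass_fir(x, fs, *params.broad_band,
                             transition=params.filter_transition_hz)
        sigma = bandpass_fir(x, fs, *params.sigma_band,
                             transition=params.filter_transition_hz)
    else:
        broad, sigma = _filtered

    # threshold 1: relative sigma power from STFT frames of the broadband trace
    hop = int(round(params.stft_hop_s * fs))
    frames, centers = _moving_frames(broad, win_stft, hop)
    win = np.hamming(win_stft)
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    freqs = np.fft.rfftfreq(win_stft, 1.0 / fs)
    sig_mask = (freqs >= params.sigma_band[0]) & (freqs <= params.sigma_band[1])
    broad_mask = (freqs >= params.broad_band[0]) & (freqs <= params.broad_band[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = spec[:, sig_mask].sum(axis=1) / spec[:, broad_mask].sum(axis=1)
    ratio = np.nan_to_num(ratio)
    rel_pow = _to_sample_grid(ratio, centers, n)

    # thresholds 2 and 3: moving correlation and moving RMS (300 ms / 100 ms)
    win_c = int(round(params.corr_window_s * fs))
    step_c = int(round(params.corr_step_s * fs))
    bf, centers_c = _moving_frames(broad, win_c, step_c)
    sf, _ = _moving_frames(sigma, win_c, step_c)
    bc = bf - bf.mean(axis=1, keepdims=True)
    sc = sf - sf.mean(axis=1, keepdims=True)
    denom = np.sqrt((bc ** 2).sum(axis=1) * (sc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (bc * sc).sum(axis=1) / denom
    r = np.nan_to_num(r)
    mcorr = _to_sample_grid(r, centers_c, n)

    rms = np.sqrt((sf ** 2).mean(axis=1))
    mrms = _to_sample_grid(rms, centers_c, n)
    rms_thresh = float(rms.mean() + params.rms_sd_factor * rms.std())
    return ThresholdSignals(rel_pow, mcorr, mrms, rms_thresh)


def _intervals_from_mask(mask):
    """(start, end) index pairs of True runs; end is exclusive."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts, ends))


def detect_spindles(segment, sampling_rate,
                    params: SpindleParams | None = None) -> list[SpindleEvent]:
    """Run the three-threshold decision rule and measure each event."""
    params = params or SpindleParams()
    x = np.asarray(segment, dtype=float)
    fs = sampling_rate
    n = x.size
    broad = bandpass_fir(x, fs, *params.broad_band,
                         transition=params.filter_transition_hz)
    sigma = bandpass_fir(x, fs, *params.sigma_band,
                         transition=params.filter_transition_hz)
    ts = compute_threshold_signals(x, fs, params, _filtered=(broad, sigma))

    count = ((ts.rel_pow >= params.rel_pow_thresh).astype(int)
             + (ts.mcorr >= params.corr_thresh).astype(int)
             + (ts.mrms >= ts.rms_thresh).astype(int))
    smooth_n = max(1, int(round(params.smooth_s * fs)))
    kernel = np.ones(smooth_n) / smooth_n
    smoothed = np.convolve(count, kernel, mode="same")

    cores = smoothed >= 2
    if not cores.any():
        return []
    raw_ok = count >= 2
    # extend each core to the surrounding run where >= 2 raw criteria hold
    spans = []
    raw_runs = _intervals_from_mask(raw_ok) if raw_ok.any() else []
    for c0, c1 in _intervals_from_mask(cores):
        s0, s1 = c0, c1
        for r0, r1 in raw_runs:
            if r0 <= c0 < r1:
                s0 = min(s0, r0)
            if r0 < c1 <= r1:
                s1 = max(s1, r1)
        spans.append([s0, s1])
    spans.sort()
    # merge events separated by less than the merge gap
    merged = [spans[0]]
    gap_n = int(round(params.merge_gap_s * fs))
    for s0, s1 in spans[1:]:
        if s0 - merged[-1][1] < gap_n:
            merged[-1][1] = max(merged[-1][1], s1)
        else:
            merged.append([s0, s1])

    # instantaneous frequency of the sigma trace, for event frequency
    phase = np.unwrap(np.angle(hilbert(sigma)))
    inst_freq = np.diff(phase) * fs / (2 * np.pi)

    events = []
    for s0, s1 in merged:
        dur = (s1 - s0) / fs
        if dur < params.min_dur_s or dur > params.max_dur_s:
            continue
        seg_sigma = sigma[s0:s1]
        amplitude = float(np.ptp(seg_sigma))
        rms = float(np.sqrt((seg_sigma ** 2).mean()))
        abspower = float(np.log10(np.median(seg_sigma ** 2) + 1e-20))
        relpower = float(ts.rel_pow[s0:s1].mean())
        frequency = float(np.clip(inst_freq[s0:max(s0 + 1, s1 - 1)].mean(), 0, fs / 2))
        upcross = np.flatnonzero((seg_sigma[:-1] < 0) & (seg_sigma[1:] >= 0))
        events.append(SpindleEvent(
            start=s0 / fs, end=s1 / fs, duration=dur, amplitude=amplitude,
            rms=rms, abspower=abspower, relpower=relpower,
            frequency=frequency, oscillations=int(upcross.size)))
    return events


def spindle_features(events, segment_duration: float) -> np.ndarray:
    """8 features: density (events/min) + means of the 7 event measures.

    Segments without events contribute zeros so the feature matrix stays
    dense; zero density is the true value there and the event means have
    no defined value.
    """
    if segment_duration <= 0:
        raise ValueError("segment_duration must be positive")
    if not events:
        return np.zeros(8)
    density = len(events) / (segment_duration / 60.0)
    cols = np.array([[e.duration, e.amplitude, e.rms, e.abspower,
                      e.relpower, e.frequency, e.oscillations]
                     for e in events])
    return np.r_[density, cols.mean(axis=0)]
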