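"""Preprocessing: filtering, resampling, hypnogram expansion, segmentation + QC.

Turns a raw two-channel recording plus a 30-s-epoch hypnogram into
quality-controlled 300-s single-channel segments labeled NREM (N2 or N3)
or wake. Artifactual segments are rejected by the standard-deviation rule:
per-segment, per-channel standard deviations are log-transformed and
z-scored, and any segment whose |z| exceeds a threshold on any channel is
dropped. Segments overlapping annotated artifact intervals are dropped
before the statistical rule is applied, as are NREM candidates containing
any non-N2/N3 sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

# AASM stage codes used throughout (one code per 30-s epoch in hypnograms)
STAGE_W = 0
STAGE_N1 = 1
STAGE_N2 = 2
STAGE_N3 = 3
STAGE_REM = 5
VALID_STAGES = frozenset({STAGE_W, STAGE_N1, STAGE_N2, STAGE_N3, STAGE_REM})

EPOCH_S = 30.0
SEGMENT_S = 300.0


@dataclass
class Recording:
    """Multi-channel EEG, channels x samples, in microvolts."""

    data: np.ndarray
    sampling_rate: float
    channels: list[str]
    subject: str = ""
    group: int | None = None  # 0 = HC, 1 = MCI

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Hypnogram:
    """Sleep-stage codes, one per 30-s epoch."""

    stages: np.ndarray
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=int)
        if self.stages.ndim != 1 or self.stages.size == 0:
            raise ValueError("hypnogram needs at least one epoch")
        bad = set(np.unique(self.stages)) - VALID_STAGES
        if bad:
            raise ValueError(f"unknown stage codes: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.stages.size

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_s


@dataclass
class EegSegment:
    """One 300-s single-channel window of EEG."""

    samples: np.ndarray
    sampling_rate: float
    channel: str
    state: str  # "NREM" or "W"
    start_s: float
    subject: str = ""
    group: int | None = None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


def bandpass_fir(x, sampling_rate, low=0.1, high=30.0, transition=None):
    """Zero-phase FIR bandpass.

    Windowed-sinc design (Hamming), transition width 0.1x the band edge
    with a 0.1 Hz floor unless overridden, applied forward-backward (zero
    phase). Output has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    nyq = sampling_rate / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz must be below Nyquist {nyq} Hz")
    trans = transition if transition is not None else max(0.1 * low, 0.1)
    numtaps = int(np.ceil(3.3 * sampling_rate / trans))
    numtaps |= 1  # odd length -> type-I linear phase
    # cap so filtfilt's padding stays feasible on short inputs
    max_taps = max(3, (x.size - 1) // 3)
    if numtaps > max_taps:
        numtaps = max_taps if max_taps % 2 == 1 else max_taps - 1
    taps = sps.firwin(numtaps, [low, high], pass_zero=False, window="hamming",
                      fs=sampling_rate)
    return sps.filtfilt(taps, [1.0], x)


def resample_to(x, from_rate, to_rate):
    """Anti-aliased downsampling (polyphase). Upsampling is refused."""
    x = np.asarray(x, dtype=float)
    if from_rate < to_rate:
        raise ValueError("pipeline only downsamples; upsampling refused")
    if from_rate == to_rate:
        return x.copy()
    frac = Fraction(to_rate).limit_denominator(1000) / Fraction(from_rate).limit_denominator(1000)
    out = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    n_expect = int(round(x.shape[-1] * to_rate / from_rate))
    return out[..., :n_expect]


def expand_hypnogram(hypnogram: Hypnogram, sampling_rate: float) -> np.ndarray:
    """Repeat each 30-s epoch code to sample resolution."""
    reps = int(round(hypnogram.epoch_s * sampling_rate))
    return np.repeat(hypnogram.stages, reps)


@dataclass
class QcReport:
    """Per-reason segment accounting for one recording."""

    n_candidates: int = 0
    n_kept: int = 0
    dropped_annotation: int = 0
    dropped_std: int = 0

    def as_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_kept": self.n_kept,
            "dropped_annotation": self.dropped_annotation,
            "dropped_std": self.dropped_std,
        }


def _eligible_windows(stage_vec, fs, codes):
    """Start indices of non-overlapping 300-s windows fully inside runs of
    the given stage codes, tiling each run left to right."""
    seg_n = int(round(SEGMENT_S * fs))
    ok = np.isin(stage_vec, list(codes))
    starts = []
    # run-length encode the eligibility mask
    edges = np.flatnonzero(np.diff(ok.astype(np.int8)))
    run_starts = np.r_[0, edges + 1]
    run_ends = np.r_[edges + 1, ok.size]
    for rs, re in zip(run_starts, run_ends):
        if not ok[rs]:
            continue
        pos = rs
        while pos + seg_n <= re:
            starts.append(pos)
            pos += seg_n
    return starts, seg_n


def candidate_windows(recording: Recording, hypnogram: Hypnogram,
                      annotations=None):
    """Annotation-clean candidate 300-s windows with their per-channel
    standard deviations.

    Returns (windows, report) where each window is a dict with state,
    start index, and the per-channel std array; ``report`` counts the
    candidates dropped by annotation overlap. The log-std z-score rule is
    applied by the caller, which chooses the pooling scope (one recording
    in :func:`segment_and_reject`; the whole cohort in
    ``features.extract_cohort_features``, where the std distribution is
    actually informative).
    """
    fs = recording.sampling_rate
    stage_vec = expand_hypnogram(hypnogram, fs)
    if stage_vec.size != recording.n_samples:
        raise ValueError(
            f"length mismatch: hypnogram expands to {stage_vec.size} samples, "
            f"recording has {recording.n_samples}")
    annotations = [] if annotations is None else list(annotations)
    report = QcReport()
    windows = []
    for state, codes in (("NREM", (STAGE_N2, STAGE_N3)), ("W", (STAGE_W,))):
        starts, seg_n = _eligible_windows(stage_vec, fs, codes)
        report.n_candidates += len(starts)
        for s0 in starts:
            t0, t1 = s0 / fs, (s0 + seg_n) / fs
            if any(a0 < t1 and a1 > t0 for a0, a1 in annotations):
                report.dropped_annotation += 1
                continue
            stds = np.array([recording.data[c, s0:s0 + seg_n].std()
                             for c in range(len(recording.channels))])
            windows.append({"state": state, "start": s0, "seg_n": seg_n,
                            "stds": stds})
    return windows, report


def log_std_outliers(stds: np.ndarray, z_thresh: float) -> np.ndarray:
    """Boolean mask of rows whose any-channel |z| of log-std exceeds the
    threshold. ``stds`` is (windows, channels); scale-free by design."""
    logs = np.log(np.maximum(np.asarray(stds, dtype=float), 1e-12))
    sd = logs.std()
    if sd == 0:
        return np.zeros(logs.shape[0], dtype=bool)
    z = (logs - logs.mean()) / sd
    return np.any(np.abs(z) > z_thresh, axis=1)


def _emit(recording, window) -> list[EegSegment]:
    s0, seg_n = window["start"], window["seg_n"]
    fs = recording.sampling_rate
    return [EegSegment(samples=recording.data[c, s0:s0 + seg_n].copy(),
                       sampling_rate=fs, channel=ch, state=window["state"],
                       start_s=s0 / fs, subject=recording.subject,
                       group=recording.group)
            for c, ch in enumerate(recording.channels)]


def segment_and_reject(recording: Recording, hypnogram: Hypnogram,
                       annotations=None, z_thresh: float = 3.0):
    """Cut 300-s NREM/W segments and reject artifacts.

    Returns (segments, report). ``annotations`` is an iterable of
    (start_s, end_s) artifact intervals; overlapping candidates are dropped
    before the log-std z-score rule. The z-scoring pools the (window,
    channel) standard deviations per state within this recording, making
    the rule invariant to global amplitude rescaling. A time window is
    kept only if every channel passes; kept windows yield one EegSegment
    per channel.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    windows, report = candidate_windows(recording, hypnogram, annotations)
    kept_segments: list[EegSegment] = []
    for state in ("NREM", "W"):
        state_windows = [w for w in windows if w["state"] == state]
        if not state_windows:
            continue
        bad = log_std_outliers(np.array([w["stds"] for w in state_windows]),
                               z_thresh)
        for w, is_bad in zip(state_windows, bad):
            if is_bad:
                report.dropped_std += 1
                continue
            kept_segments.extend(_emit(recording, w))
            report.n_kept += 1
    return kept_segments, report


def preprocess_recording(recording: Recording, low=0.1, high=30.0,
                         target_rate=100.0) -> Recording:
    """Bandpass at the native rate, then downsample: the standard front end."""
    filtered = np.vstack([bandpass_fir(row, recording.sampling_rate, low, high)
                          for row in recording.data])
    if recording.sampling_rate != target_rate:
        filtered = np.vstack([resample_to(row, recording.sampling_rate, target_rate)
                              for row in filtered])
    return Recording(filtered, target_rate, list(recording.channels),
                     recording.subject, recording.group)
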