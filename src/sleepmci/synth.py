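"""Synthetic sleep-EEG cohort generator.

Produces reproducible two-channel recordings with hypnograms and
ground-truth event lists carrying the group-level structure the analysis
assumes: MCI recordings have fewer spindles, smaller/rarer slow waves and
elevated relative theta power compared with healthy controls.

Background EEG is spectrally shaped Gaussian noise (1/f^beta). Spindles
(11-16 Hz bursts under a raised-cosine envelope) and slow waves (a negative
then a positive half-wave) are superimposed on the background at Poisson
rates inside their eligible stages (spindles in N2, slow waves in N2+N3).
Movement artifacts are high-amplitude 1-3 s transients used to exercise
the std-rejection QC stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import (EPOCH_S, STAGE_N2, STAGE_N3, Hypnogram, Recording,
                         bandpass_fir)

# default stage schedule: ~35 min with wake bracketing a N2/N3 sleep block
DEFAULT_SCHEDULE = [
    ("W", 330.0),
    ("N1", 60.0),
    ("N2", 630.0),
    ("N3", 330.0),
    ("N2", 330.0),
    ("REM", 90.0),
    ("W", 330.0),
]

STAGE_CODES = {"W": 0, "N1": 1, "N2": 2, "N3": 3, "REM": 5}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    sampling_rate: float = 100.0
    channels: tuple[str, ...] = ("C3", "C4")
    stage_schedule: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_SCHEDULE))
    noise_exponent: float = 1.0     # beta of 1/f^beta background
    noise_scale: float = 10.0       # uV RMS of background
    spindle_rate: float = 2.0       # events/min in N2, healthy controls
    sw_rate: float = 4.0            # events/min in N2+N3, healthy controls
    spindle_freq_range: tuple[float, float] = (12.0, 14.0)
    spindle_amp: float = 25.0       # uV envelope peak
    spindle_dur_range: tuple[float, float] = (0.6, 1.5)
    sw_ptp_range: tuple[float, float] = (100.0, 250.0)
    mci_spindle_factor: float = 0.5
    mci_sw_factor: float = 0.7      # multiplies both sw rate and PTP
    mci_theta_boost: float = 1.5    # gain on the 4-8 Hz background component
    artifact_rate: float = 2.0      # events/hour, shared across channels
    artifact_amp_factor: float = 100.0  # x noise_scale: mV-scale movement/
                                        # electrode transients
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 100:
            raise ValueError("sampling_rate must be >= 100 Hz")
        for name in ("spindle_rate", "sw_rate", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.spindle_freq_range
        if not (11.0 <= lo < hi <= 16.0):
            raise ValueError("spindle_freq_range must lie within [11, 16] Hz")
        for stage, dur in self.stage_schedule:
            if stage not in STAGE_CODES:
                raise ValueError(f"unknown stage {stage!r}")
            if dur <= 0 or abs(dur / EPOCH_S - round(dur / EPOCH_S)) > 1e-9:
                raise ValueError("stage durations must be positive multiples of 30 s")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.stage_schedule))


@dataclass
class GroundTruth:
    """Injected events per channel: dicts channel -> list of event tuples."""

    spindles: dict[str, list[tuple[float, float, float, float]]]  # start, end, freq, amp
    slow_waves: dict[str, list[tuple[float, float, float]]]       # start, end, ptp
    artifacts: dict[str, list[tuple[float, float]]]               # start, end

    def artifact_annotations(self) -> list[tuple[float, float]]:
        """Union of artifact intervals over channels, sorted — the
        synthetic stand-in for a recording's manual artifact annotations."""
        seen = {iv for events in self.artifacts.values() for iv in events}
        return sorted(seen)


def colored_noise(n: int, beta: float, scale: float, seed) -> np.ndarray:
    """Zero-mean Gaussian noise with a 1/f^beta power spectrum, RMS = scale.

    Shaped in the frequency domain: white Gaussian spectrum multiplied by
    f^(-beta/2); the DC component is zeroed. ``seed`` may be an int or a
    numpy Generator.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0)  # unit grid; absolute Hz is irrelevant to the slope
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    rms = x.std()
    if rms > 0:
        x *= scale / rms
    return x


def synth_spindle(freq: float, duration: float, amplitude: float,
                  sampling_rate: float) -> np.ndarray:
    """Sinusoid at ``freq`` under a raised-cosine (Hann) envelope.

    Endpoints are ~0 and the envelope maximum reaches ``amplitude``.
    """
    if not (11.0 <= freq <= 16.0):
        raise ValueError("spindle frequency must be within [11, 16] Hz")
    if duration < 0.5:
        raise ValueError("spindle duration must be >= 0.5 s")
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    envelope = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))
    # phase chosen so a carrier peak lands on the envelope maximum
    carrier = np.cos(2 * np.pi * freq * (t - t[n // 2]))
    return amplitude * envelope * carrier


def slow_wave_shape(ptp: float, neg_dur: float, pos_dur: float,
                    sampling_rate: float) -> np.ndarray:
    """Unchecked slow-wave template: negative then positive half-sine.

    The trough takes 5/8 of the trough-to-peak amplitude and the positive
    peak 3/8, keeping both inside the detector's per-peak amplitude
    windows over the whole admissible PTP range. Used directly by
    detector-characterization sweeps that probe out-of-range parameters.
    """
    n_neg = int(round(neg_dur * sampling_rate))
    n_pos = int(round(pos_dur * sampling_rate))
    a_neg = ptp * 5.0 / 8.0
    a_pos = ptp * 3.0 / 8.0
    neg = -a_neg * np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = a_pos * np.sin(np.pi * np.arange(n_pos) / n_pos)
    return np.concatenate([neg, pos])


def synth_slow_wave(ptp: float, neg_dur: float, pos_dur: float,
                    sampling_rate: float) -> np.ndarray:
    """Negative half-sine of ``neg_dur`` followed by a positive one of
    ``pos_dur``; trough-to-peak amplitude equals ``ptp``."""
    if ptp <= 0:
        raise ValueError("ptp must be positive")
    if not (0.3 <= neg_dur <= 1.5):
        raise ValueError("neg_dur must be within [0.3, 1.5] s")
    if not (0.1 <= pos_dur <= 1.0):
        raise ValueError("pos_dur must be within [0.1, 1] s")
    return slow_wave_shape(ptp, neg_dur, pos_dur, sampling_rate)


def _schedule_to_hypnogram(schedule) -> Hypnogram:
    codes = []
    for stage, dur in schedule:
        codes.extend([STAGE_CODES[stage]] * int(round(dur / EPOCH_S)))
    return Hypnogram(np.array(codes, dtype=int))


def _eligible_epochs(hypnogram: Hypnogram, codes) -> np.ndarray:
    return np.flatnonzero(np.isin(hypnogram.stages, list(codes)))


def _place_events(rng, hypnogram, stage_codes, rate_per_min, dur_sampler,
                  max_tries=50):
    """Poisson placement of non-overlapping events, each fully inside one
    eligible 30-s epoch. Returns list of (start_s, dur_s)."""
    epochs = _eligible_epochs(hypnogram, stage_codes)
    if epochs.size == 0 or rate_per_min <= 0:
        return []
    eligible_min = epochs.size * EPOCH_S / 60.0
    n_events = rng.poisson(rate_per_min * eligible_min)
    placed = []
    for _ in range(n_events):
        dur = dur_sampler()
        for _ in range(max_tries):
            ep = epochs[rng.integers(epochs.size)]
            t0 = ep * EPOCH_S + rng.uniform(0.0, EPOCH_S - dur)
            if all(t0 + dur <= s or t0 >= s + d for s, d in placed):
                placed.append((t0, dur))
                break
    placed.sort()
    return placed


def generate_recording(config: SimulationConfig, is_mci: bool, subject: str,
                       seed) -> tuple[Recording, Hypnogram, GroundTruth]:
    """One synthetic recording with its hypnogram and ground truth."""
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    hyp = _schedule_to_hypnogram(config.stage_schedule)
    n = int(round(hyp.duration * fs))

    sp_rate = config.spindle_rate * (config.mci_spindle_factor if is_mci else 1.0)
    sw_rate = config.sw_rate * (config.mci_sw_factor if is_mci else 1.0)
    ptp_lo, ptp_hi = config.sw_ptp_range
    if is_mci:
        ptp_lo, ptp_hi = ptp_lo * config.mci_sw_factor, ptp_hi * config.mci_sw_factor

    data = np.empty((len(config.channels), n))
    spindles: dict[str, list] = {}
    slow_waves: dict[str, list] = {}
    artifacts: dict[str, list] = {}

    # movement artifacts are global events: one placement, all channels
    art_events = []
    art_waves = []
    rate_min = config.artifact_rate / 60.0
    for t0, dur in _place_events(rng, hyp, tuple(STAGE_CODES.values()),
                                 rate_min, lambda: rng.uniform(1.0, 3.0)):
        m = int(round(dur * fs))
        t = np.arange(m) / fs
        blob = (config.artifact_amp_factor * config.noise_scale
                * np.hanning(m) * np.sign(np.sin(2 * np.pi * 1.5 * t) + 1e-12))
        art_events.append((t0, t0 + dur))
        art_waves.append((int(round(t0 * fs)), blob))

    for c, ch in enumerate(config.channels):
        x = colored_noise(n, config.noise_exponent, config.noise_scale, rng)
        if is_mci and config.mci_theta_boost != 1.0:
            theta = bandpass_fir(x, fs, 4.0, 8.0)
            x = x + (config.mci_theta_boost - 1.0) * theta

        sp_events = []
        d_lo, d_hi = config.spindle_dur_range
        for t0, dur in _place_events(rng, hyp, (STAGE_N2,), sp_rate,
                                     lambda: rng.uniform(d_lo, d_hi)):
            f_lo, f_hi = config.spindle_freq_range
            freq = rng.uniform(f_lo, f_hi)
            burst = synth_spindle(freq, dur, config.spindle_amp, fs)
            i0 = int(round(t0 * fs))
            x[i0:i0 + burst.size] += burst[:n - i0]
            sp_events.append((t0, t0 + dur, freq, config.spindle_amp))

        sw_events = []
        for t0, dur in _place_events(
                rng, hyp, (STAGE_N2, STAGE_N3), sw_rate,
                lambda: rng.uniform(0.4, 1.5) + rng.uniform(0.15, 0.8)):
            neg = min(max(dur * 0.6, 0.3), 1.5)
            pos = min(max(dur - neg, 0.1), 1.0)
            ptp = rng.uniform(ptp_lo, ptp_hi)
            wave = synth_slow_wave(ptp, neg, pos, fs)
            i0 = int(round(t0 * fs))
            x[i0:i0 + wave.size] += wave[:n - i0]
            sw_events.append((t0, t0 + neg + pos, ptp))

        for i0, blob in art_waves:
            x[i0:i0 + blob.size] += blob[:n - i0]

        data[c] = x
        spindles[ch] = sp_events
        slow_waves[ch] = sw_events
        artifacts[ch] = art_events

    rec = Recording(data, fs, list(config.channels), subject,
                    group=int(is_mci))
    return rec, hyp, GroundTruth(spindles, slow_waves, artifacts)


def generate_cohort(config: SimulationConfig, n_hc: int, n_mci: int):
    """Full cohort: returns (recordings, hypnograms, truths, labels)."""
    if n_hc < 1 or n_mci < 1:
        raise ValueError("need at least one subject per group")
    if not config.stage_schedule:
        raise ValueError("stage schedule must contain at least one epoch")
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(n_hc + n_mci)
    recordings, hypnograms, truths, labels = [], [], [], []
    for i, child in enumerate(child_seeds):
        is_mci = i >= n_hc
        subject = f"{'mci' if is_mci else 'hc'}{(i - n_hc if is_mci else i) + 1:03d}"
        rec, hyp, truth = generate_recording(config, is_mci, subject, child)
        recordings.append(rec)
        hypnograms.append(hyp)
        truths.append(truth)
        labels.append(int(is_mci))
    return recordings, hypnograms, truths, labels
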