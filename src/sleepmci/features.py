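"""Per-segment feature assembly, channel fusion and standardization.

Each 300-s time window yields one feature row: the 13 spectral and 8
complexity features are computed per channel and averaged across C3/C4;
NREM rows additionally carry the 8 spindle and 7 slow-wave features
(36 features total), wake rows carry spectral + complexity only (21).
Averaging is the only two-channel fusion consistent with a 36-wide NREM
vector. Standardization is z-scoring with means/SDs estimated on training
rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import complexity, slowwaves, spectral, spindles
from .preprocess import (EegSegment, Hypnogram, Recording,
                         candidate_windows, log_std_outliers)

NREM_FEATURES = (spectral.SPECTRAL_FEATURE_NAMES + complexity.FEATURE_NAMES
                 + spindles.FEATURE_NAMES + slowwaves.FEATURE_NAMES)
WAKE_FEATURES = spectral.SPECTRAL_FEATURE_NAMES + complexity.FEATURE_NAMES

assert len(NREM_FEATURES) == 36 and len(WAKE_FEATURES) == 21


@dataclass
class FeatureTable:
    """Segments x features matrix with row metadata."""

    values: pd.DataFrame                  # numeric features only
    meta: pd.DataFrame                    # subject, group, state, start_s
    state: str                            # "NREM" or "W"
    standardized: bool = False
    means: pd.Series | None = None
    sds: pd.Series | None = None
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = NREM_FEATURES if self.state == "NREM" else WAKE_FEATURES
        if list(self.values.columns) != expected:
            raise ValueError("feature columns do not match the frozen contract")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("feature table contains non-finite entries")

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.meta["group"].to_numpy().astype(int)

    @property
    def n_rows(self) -> int:
        return len(self.values)


def segment_features(segment: EegSegment,
                     welch: spectral.WelchParams | None = None,
                     bands: spectral.BandScheme | None = None,
                     cparams: complexity.ComplexityParams | None = None,
                     sp_params: spindles.SpindleParams | None = None,
                     sw_params: slowwaves.SlowWaveParams | None = None):
    """All features of one single-channel segment, in contract order."""
    freqs, psd = spectral.welch_psd(segment.samples, segment.sampling_rate, welch)
    spec = spectral.band_powers(freqs, psd, bands)
    comp, flags = complexity.compute_complexity(segment.samples, cparams)
    if segment.state == "NREM":
        sp_events = spindles.detect_spindles(segment.samples,
                                             segment.sampling_rate, sp_params)
        sw_events = slowwaves.detect_slow_waves(segment.samples,
                                                segment.sampling_rate, sw_params)
        vec = np.r_[spec, comp,
                    spindles.spindle_features(sp_events, segment.duration),
                    slowwaves.slow_wave_features(sw_events, segment.duration)]
    else:
        vec = np.r_[spec, comp]
    return vec, flags


def assemble_features(channel_vectors: dict[str, np.ndarray], state: str,
                      allow_single_channel: bool = True):
    """Fuse per-channel vectors of one time window by averaging.

    Returns (vector, flags). With one channel missing the other is used
    as-is (flagged) when ``allow_single_channel``; otherwise this raises.
    """
    width = 36 if state == "NREM" else 21
    vecs = [v for v in channel_vectors.values() if v is not None]
    flags = []
    if not vecs:
        raise ValueError("no channel feature vectors supplied")
    if len(vecs) < len(channel_vectors):
        if not allow_single_channel:
            raise ValueError("missing channel and single-channel fallback disabled")
        flags.append("single_channel_fallback")
    for v in vecs:
        if v.size != width:
            raise ValueError(f"expected {width} features for state {state}, got {v.size}")
    return np.mean(vecs, axis=0), flags


def extract_cohort_features(recordings: list[Recording],
                            hypnograms: list[Hypnogram],
                            annotations=None, z_thresh: float = 3.0,
                            **kwargs) -> dict[str, FeatureTable]:
    """Run segmentation + QC + feature extraction over a cohort.

    The log-std z-score artifact rule is applied per state over the
    pooled candidate windows of the *whole cohort*: the std distribution
    of a single short recording has too few windows for a 3-SD cut to be
    meaningful, while the pooled distribution matches how a full study
    population is screened.

    Returns {"NREM": FeatureTable, "W": FeatureTable}; a state with no
    surviving segments is omitted.
    """
    per_rec = []
    for i, (rec, hyp) in enumerate(zip(recordings, hypnograms)):
        ann = annotations[i] if annotations is not None else None
        wins, _ = candidate_windows(rec, hyp, ann)
        per_rec.append(wins)
    # pooled rejection per state
    keep: dict[int, list] = {i: [] for i in range(len(recordings))}
    for state in ("NREM", "W"):
        flat = [(i, w) for i, wins in enumerate(per_rec) for w in wins
                if w["state"] == state]
        if not flat:
            continue
        bad = log_std_outliers(np.array([w["stds"] for _, w in flat]),
                               z_thresh)
        for (i, w), is_bad in zip(flat, bad):
            if not is_bad:
                keep[i].append(w)

    rows: dict[str, list] = {"NREM": [], "W": []}
    meta: dict[str, list] = {"NREM": [], "W": []}
    all_flags: list[str] = []
    for i, rec in enumerate(recordings):
        # group per time window across channels
        windows: dict[tuple[str, float], dict[str, EegSegment]] = {}
        for w in keep[i]:
            fs = rec.sampling_rate
            for c, ch in enumerate(rec.channels):
                seg = EegSegment(
                    samples=rec.data[c, w["start"]:w["start"] + w["seg_n"]].copy(),
                    sampling_rate=fs, channel=ch, state=w["state"],
                    start_s=w["start"] / fs, subject=rec.subject,
                    group=rec.group)
                windows.setdefault((seg.state, seg.start_s), {})[ch] = seg
        for (state, start_s), chans in sorted(windows.items()):
            per_channel = {}
            for ch, seg in chans.items():
                vec, flags = segment_features(seg, **kwargs)
                per_channel[ch] = vec
                all_flags.extend(flags)
            fused, flags = assemble_features(per_channel, state)
            all_flags.extend(flags)
            rows[state].append(fused)
            meta[state].append({"subject": rec.subject, "group": rec.group,
                                "state": state, "start_s": start_s})
    out = {}
    for state, names in (("NREM", NREM_FEATURES), ("W", WAKE_FEATURES)):
        if rows[state]:
            out[state] = FeatureTable(
                values=pd.DataFrame(rows[state], columns=names),
                meta=pd.DataFrame(meta[state]), state=state,
                qc_flags=all_flags)
    return out


def standardize(table: FeatureTable, train_rows) -> FeatureTable:
    """Z-score all rows with means/SDs estimated on ``train_rows`` only.

    A feature constant on the training rows gets SD 1 (flagged), producing
    an all-zero column rather than NaNs.
    """
    train_rows = np.asarray(train_rows)
    if train_rows.size == 0:
        raise ValueError("training row set is empty")
    train = table.values.iloc[train_rows]
    means = train.mean()
    sds = train.std(ddof=0)
    flags = list(table.qc_flags)
    zero_sd = sds[sds == 0].index.tolist()
    for name in zero_sd:
        flags.append(f"constant_train_feature:{name}")
        sds[name] = 1.0
    values = (table.values - means) / sds
    return FeatureTable(values=values, meta=table.meta.copy(), state=table.state,
                        standardized=True, means=means, sds=sds, qc_flags=flags)
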