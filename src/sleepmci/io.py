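"""File formats: EDF, hypnogram text, event/annotation CSV, QC TSV.

Writing uses a minimal 16-bit EDF writer (physical unit uV, 1-s data
records); reading goes through ``mne.io.read_raw_edf`` so anything the
writer produces is validated against an independent parser. Hypnograms
are one stage code per line per 30-s epoch (W=0, N1=1, N2=2, N3=3,
REM=5). Ground truth and annotations are plain CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Hypnogram, QcReport, Recording
from .synth import GroundTruth


def _pad(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, recording: Recording) -> None:
    """16-bit EDF, physical unit uV, 1-s data records.

    The signal is truncated to a whole number of records (recordings are
    multiples of 30 s, so nothing is lost in practice).
    """
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))  # samples per 1-s record
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = recording.n_samples // spr
    ns = len(recording.channels)
    data = recording.data[:, :n_records * spr]

    phys_min = np.floor(data.min(axis=1))
    phys_max = np.ceil(data.max(axis=1))
    phys_max = np.where(phys_max <= phys_min, phys_min + 1, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _pad("0", 8),
        _pad(recording.subject or "X", 80),
        _pad("Startdate 01-JAN-2000", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
        b"".join(_pad(f"EEG {ch}", 16) for ch in recording.channels),
        b"".join(_pad("", 80) for _ in range(ns)),
        b"".join(_pad("uV", 8) for _ in range(ns)),
        b"".join(_pad(f"{phys_min[i]:g}", 8) for i in range(ns)),
        b"".join(_pad(f"{phys_max[i]:g}", 8) for i in range(ns)),
        b"".join(_pad(str(dig_min), 8) for _ in range(ns)),
        b"".join(_pad(str(dig_max), 8) for _ in range(ns)),
        b"".join(_pad("", 80) for _ in range(ns)),
        b"".join(_pad(str(spr), 8) for _ in range(ns)),
        b"".join(_pad("", 32) for _ in range(ns)),
    ])

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for c in range(ns):
                chunk = data[c, r * spr:(r + 1) * spr]
                dig = np.round((chunk - phys_min[c]) * scale[c] + dig_min)
                fh.write(dig.astype("<i2").tobytes())


def read_edf(path, subject: str = "", group=None) -> Recording:
    """Load an EDF through mne, returning samples in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne uses volts internally
    channels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    return Recording(data, float(raw.info["sfreq"]), channels,
                     subject=subject, group=group)


def write_hypnogram(path, hypnogram: Hypnogram) -> None:
    Path(path).write_text("\n".join(str(int(s)) for s in hypnogram.stages) + "\n")


def read_hypnogram(path) -> Hypnogram:
    codes = [int(line) for line in Path(path).read_text().split()]
    return Hypnogram(np.array(codes, dtype=int))


def write_ground_truth(path, truth: GroundTruth) -> None:
    """CSV with columns channel, type, start_s, end_s, param (freq or ptp)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "type", "start_s", "end_s", "param"])
        for ch, events in truth.spindles.items():
            for start, end, freq, _amp in events:
                w.writerow([ch, "spindle", f"{start:.3f}", f"{end:.3f}", f"{freq:.2f}"])
        for ch, events in truth.slow_waves.items():
            for start, end, ptp in events:
                w.writerow([ch, "slow_wave", f"{start:.3f}", f"{end:.3f}", f"{ptp:.1f}"])
        for ch, events in truth.artifacts.items():
            for start, end in events:
                w.writerow([ch, "artifact", f"{start:.3f}", f"{end:.3f}", ""])


def read_truth_artifacts(path) -> list[tuple[float, float]]:
    """Artifact intervals from a ground-truth CSV (union over channels)."""
    df = pd.read_csv(path)
    rows = df[df["type"] == "artifact"]
    return sorted({(float(r.start_s), float(r.end_s))
                   for r in rows.itertuples()})


def read_annotations(path) -> list[tuple[float, float]]:
    """CSV intervals (start_s, end_s[, label]) -> list of (start, end)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower().startswith("start"):
                continue
            out.append((float(row[0]), float(row[1])))
    return out


def write_qc_report(path, reports: dict[str, QcReport]) -> None:
    rows = [{"subject": k, **r.as_dict()} for k, r in reports.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_events_csv(path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)
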