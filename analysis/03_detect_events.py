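"""Detect spindles and slow waves on the preprocessed cohort.

Runs both detectors over every kept NREM segment, writes the event tables
(results/spindle_events.csv, results/slow_wave_events.csv) and scores the
spindle detector against the injected ground truth (an event counts as
recovered when detection and truth overlap by at least half the injected
duration).

Usage: python analysis/03_detect_events.py
"""

from pathlib import Path

import pandas as pd

from sleepmci import io as smio
from sleepmci.preprocess import preprocess_recording, segment_and_reject
from sleepmci.slowwaves import detect_slow_waves
from sleepmci.spindles import detect_spindles

cohort_dir = Path("results/cohort")
edfs = sorted(cohort_dir.glob("*.edf"))
if not edfs:
    raise SystemExit("run analysis/01_simulate_cohort.py first")

sp_rows, sw_rows = [], []
n_truth = n_hit = n_det = 0
for edf in edfs:
    subject = edf.stem
    rec = smio.read_edf(edf, subject=subject,
                        group=int(subject.startswith("mci")))
    hyp = smio.read_hypnogram(edf.with_suffix(".hypno.txt"))
    truth = pd.read_csv(edf.with_suffix(".truth.csv"))
    ann = smio.read_truth_artifacts(edf.with_suffix(".truth.csv"))
    rec = preprocess_recording(rec)
    segments, _ = segment_and_reject(rec, hyp, ann)
    for si, seg in enumerate(s for s in segments if s.state == "NREM"):
        t0 = seg.start_s
        spindles = detect_spindles(seg.samples, seg.sampling_rate)
        for e in spindles:
            sp_rows.append({"subject": subject, "channel": seg.channel,
                            "segment": si, "start_s": t0 + e.start,
                            "end_s": t0 + e.end, "duration": e.duration,
                            "amplitude": e.amplitude, "rms": e.rms,
                            "abspower": e.abspower, "relpower": e.relpower,
                            "frequency": e.frequency,
                            "oscillations": e.oscillations})
        for e in detect_slow_waves(seg.samples, seg.sampling_rate):
            sw_rows.append({"subject": subject, "channel": seg.channel,
                            "segment": si, "start_s": t0 + e.start,
                            "end_s": t0 + e.end, "duration": e.duration,
                            "val_neg_peak": e.val_neg_peak,
                            "val_pos_peak": e.val_pos_peak, "ptp": e.ptp,
                            "slope": e.slope, "frequency": e.frequency})
        # score spindle recovery inside this segment window
        tr = truth[(truth.type == "spindle") & (truth.channel == seg.channel)
                   & (truth.start_s >= t0) & (truth.end_s <= t0 + seg.duration)]
        n_truth += len(tr)
        n_det += len(spindles)
        for _, row in tr.iterrows():
            dur = row.end_s - row.start_s
            for e in spindles:
                lo = max(row.start_s, t0 + e.start)
                hi = min(row.end_s, t0 + e.end)
                if hi - lo >= 0.5 * dur:
                    n_hit += 1
                    break

out = Path("results")
pd.DataFrame(sp_rows).to_csv(out / "spindle_events.csv", index=False)
pd.DataFrame(sw_rows).to_csv(out / "slow_wave_events.csv", index=False)
recall = n_hit / n_truth if n_truth else float("nan")
print(f"spindles: {len(sp_rows)} detected, {n_truth} injected in kept NREM "
      f"segments, recall {recall:.2f}")
print(f"slow waves: {len(sw_rows)} detected")
print(f"event tables written to {out}")
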