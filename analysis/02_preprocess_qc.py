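"""Preprocess the simulated cohort and report segment QC.

Loads the EDFs written by 01_simulate_cohort.py, bandpasses 0.1-30 Hz,
cuts 300-s NREM and wake candidate windows, applies the log-std z-score
artifact rule pooled over the whole cohort (per state), and writes the
per-subject QC table to results/qc_report.tsv.

Usage: python analysis/02_preprocess_qc.py
"""

from pathlib import Path

import numpy as np

from sleepmci import io as smio
from sleepmci.preprocess import (QcReport, candidate_windows,
                                 log_std_outliers, preprocess_recording)

cohort_dir = Path("results/cohort")
out = Path("results")
edfs = sorted(cohort_dir.glob("*.edf"))
if not edfs:
    raise SystemExit("run analysis/01_simulate_cohort.py first")

reports: dict[str, QcReport] = {}
per_rec = []
for edf in edfs:
    subject = edf.stem
    rec = smio.read_edf(edf, subject=subject,
                        group=int(subject.startswith("mci")))
    hyp = smio.read_hypnogram(edf.with_suffix(".hypno.txt"))
    ann = smio.read_truth_artifacts(edf.with_suffix(".truth.csv"))
    rec = preprocess_recording(rec)
    wins, report = candidate_windows(rec, hyp, ann)
    reports[subject] = report
    per_rec.append((subject, wins))

n_kept = {"NREM": 0, "W": 0}
for state in ("NREM", "W"):
    flat = [(subj, w) for subj, wins in per_rec for w in wins
            if w["state"] == state]
    if not flat:
        continue
    bad = log_std_outliers(np.array([w["stds"] for _, w in flat]), 3.0)
    for (subj, _w), is_bad in zip(flat, bad):
        if is_bad:
            reports[subj].dropped_std += 1
        else:
            reports[subj].n_kept += 1
            n_kept[state] += 1

smio.write_qc_report(out / "qc_report.tsv", reports)
total = sum(r.n_candidates for r in reports.values())
kept = sum(r.n_kept for r in reports.values())
dropped_std = sum(r.dropped_std for r in reports.values())
dropped_ann = sum(r.dropped_annotation for r in reports.values())
print(f"{len(edfs)} recordings -> {total} candidate 300-s windows, "
      f"{kept} kept ({dropped_ann} dropped by artifact annotations, "
      f"{dropped_std} by the pooled log-std z-score rule)")
print(f"kept windows: NREM {n_kept['NREM']}, wake {n_kept['W']}")
print(f"QC table: {out / 'qc_report.tsv'}")
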