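"""Extract the per-segment feature tables.

Computes the full feature set for every kept segment — 13 spectral + 8
complexity per channel, plus 8 spindle + 7 slow-wave features for NREM —
fuses C3/C4 by averaging and writes results/features_nrem.tsv (36
feature columns) and results/features_wake.tsv (21 columns), plus a run
manifest recording the parameter choices.

Usage: python analysis/04_extract_features.py
"""

import json
from dataclasses import asdict
from pathlib import Path

from sleepmci import io as smio
from sleepmci.complexity import ComplexityParams
from sleepmci.features import extract_cohort_features
from sleepmci.preprocess import preprocess_recording
from sleepmci.slowwaves import SlowWaveParams
from sleepmci.spectral import WelchParams
from sleepmci.spindles import SpindleParams

cohort_dir = Path("results/cohort")
edfs = sorted(cohort_dir.glob("*.edf"))
if not edfs:
    raise SystemExit("run analysis/01_simulate_cohort.py first")

recordings, hypnograms, annotations = [], [], []
for edf in edfs:
    subject = edf.stem
    rec = smio.read_edf(edf, subject=subject,
                        group=int(subject.startswith("mci")))
    recordings.append(preprocess_recording(rec))
    hypnograms.append(smio.read_hypnogram(edf.with_suffix(".hypno.txt")))
    annotations.append(smio.read_truth_artifacts(edf.with_suffix(".truth.csv")))

tables = extract_cohort_features(recordings, hypnograms,
                                 annotations=annotations)

out = Path("results")
for state, fname in (("NREM", "features_nrem.tsv"), ("W", "features_wake.tsv")):
    table = tables[state]
    df = table.meta.join(table.values)
    df.to_csv(out / fname, sep="\t", index=False)
    print(f"{state}: {table.n_rows} segments x {table.values.shape[1]} features "
          f"-> {out / fname}")

manifest = {
    "welch": asdict(WelchParams()),
    "spindle": asdict(SpindleParams()),
    "slow_wave": asdict(SlowWaveParams()),
    "complexity": asdict(ComplexityParams()),
    "n_recordings": len(recordings),
}
(out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
print(f"parameter manifest -> {out / 'run_manifest.json'}")
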