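"""Group comparison of relative band powers (Mann-Whitney U).

For each band and state, compares HC vs MCI relative power with a
two-sided Mann-Whitney U test, marks significance (* p<0.05, ** p<0.01),
writes results/band_comparisons.tsv and a grouped bar plot.

Usage: python analysis/06_band_stats.py
"""

from pathlib import Path

import pandas as pd

from sleepmci.features import NREM_FEATURES, WAKE_FEATURES, FeatureTable
from sleepmci.stats import REL_BANDS, compare_bands, comparisons_to_frame

out = Path("results")
tables = {}
for state, fname, cols in (("NREM", "features_nrem.tsv", NREM_FEATURES),
                           ("W", "features_wake.tsv", WAKE_FEATURES)):
    path = out / fname
    if not path.exists():
        raise SystemExit("run analysis/04_extract_features.py first")
    df = pd.read_csv(path, sep="\t")
    tables[state] = FeatureTable(
        values=df[cols], meta=df[["subject", "group", "state", "start_s"]],
        state=state)

results = compare_bands(tables)
frame = comparisons_to_frame(results)
frame.to_csv(out / "band_comparisons.tsv", sep="\t", index=False)
for r in results:
    print(f"{r.state:4s} {r.band:6s}: U={r.u_stat:8.1f} p={r.p_value:.2e} {r.marker}")
print(f"table -> {out / 'band_comparisons.tsv'}")

# bar plot of group-mean relative power per band, mirroring the usual figure
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
for ax, (state, table) in zip(axes, tables.items()):
    means = {g: [table.values[f"relpow_{b}"][table.y == g].mean()
                 for b in REL_BANDS] for g in (0, 1)}
    x = range(len(REL_BANDS))
    ax.bar([i - 0.2 for i in x], means[0], width=0.4, label="HC")
    ax.bar([i + 0.2 for i in x], means[1], width=0.4, label="MCI")
    markers = {r.band: r.marker for r in results if r.state == state}
    for i, b in enumerate(REL_BANDS):
        if markers[b] != "ns":
            ax.text(i, max(means[0][i], means[1][i]) * 1.05, markers[b],
                    ha="center")
    ax.set_xticks(list(x), REL_BANDS)
    ax.set_title(state)
    ax.set_ylabel("relative power")
    ax.legend()
fig.tight_layout()
fig.savefig(out / "band_comparisons.png", dpi=120)
print(f"figure -> {out / 'band_comparisons.png'}")
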