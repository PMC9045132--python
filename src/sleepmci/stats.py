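"""Group-level nonparametric comparison of relative band powers.

For each frequency band and vigilance state, the relative powers of the
two groups are compared with a two-sided Mann-Whitney U test (normal
approximation with tie correction for larger samples). Significance
markers: ``*`` for p < 0.05, ``**`` for p < 0.01, ``ns`` otherwise. No
multiple-testing correction is applied by default; a Bonferroni option
is exposed. Observations are segments by default; a subject-mean mode is
provided because segments within a subject are not independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .features import FeatureTable

REL_BANDS = ["delta", "theta", "alpha", "sigma", "beta", "gamma"]


@dataclass
class GroupComparison:
    band: str
    state: str
    u_stat: float
    p_value: float
    marker: str
    n_hc: int
    n_mci: int


def significance_marker(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_bands(tables: dict[str, FeatureTable],
                  observations: str = "segment",
                  bonferroni: bool = False) -> list[GroupComparison]:
    """Mann-Whitney U per band per state on relative powers.

    ``tables`` maps state name ("NREM"/"W") to its FeatureTable.
    """
    results: list[GroupComparison] = []
    n_tests = sum(len(REL_BANDS) for _ in tables)
    for state, table in tables.items():
        y = table.y
        if (y == 0).sum() == 0 or (y == 1).sum() == 0:
            raise ValueError("both groups must be non-empty")
        for band in REL_BANDS:
            col = table.values[f"relpow_{band}"]
            if observations == "subject":
                df = pd.DataFrame({"v": col.to_numpy(),
                                   "subject": table.meta["subject"],
                                   "group": y})
                agg = df.groupby("subject").agg(v=("v", "mean"),
                                                group=("group", "first"))
                hc = agg.loc[agg["group"] == 0, "v"].to_numpy()
                mci = agg.loc[agg["group"] == 1, "v"].to_numpy()
            elif observations == "segment":
                hc = col.to_numpy()[y == 0]
                mci = col.to_numpy()[y == 1]
            else:
                raise ValueError("observations must be 'segment' or 'subject'")
            u, p = mannwhitneyu(hc, mci, alternative="two-sided")
            if bonferroni:
                p = min(1.0, p * n_tests)
            results.append(GroupComparison(
                band=band, state=state, u_stat=float(u), p_value=float(p),
                marker=significance_marker(p), n_hc=hc.size, n_mci=mci.size))
    return results


def comparisons_to_frame(results: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
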