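#!/usr/bin/env python
"""Unpaired t-tests of per-side cumulative enrichment, with violin panels.

High_exp vs Low_exp over asymmetric pairs and Similar_left vs
Similar_right over symmetric expressed pairs, for every mark; silent
pairs are excluded.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from bidiprom.pipeline import run_compare

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    outdir = ROOT / "results" / "stats"
    comparisons = run_compare(
        ROOT / "results" / "profiles" / "side_enrichment.tsv",
        ROOT / "results" / "classes" / "classes.tsv",
        outdir,
    )
    print(comparisons.to_string(index=False))

    values = pd.read_csv(outdir / "violin_values.tsv", sep="\t")
    marks = sorted(values["mark"].unique())
    fig, axes = plt.subplots(2, len(marks), figsize=(3 * len(marks), 7), squeeze=False)
    for j, mark in enumerate(marks):
        for i, comparison in enumerate(("asymmetric", "symmetric")):
            ax = axes[i][j]
            sub = values[(values["mark"] == mark) & (values["comparison"] == comparison)]
            if sub.empty:
                ax.axis("off")
                continue
            groups = sorted(sub["group"].unique())
            data = [sub.loc[sub["group"] == g, "value"] for g in groups]
            ax.violinplot(data, showmedians=True)
            ax.set_xticks(np.arange(1, len(groups) + 1), groups, fontsize=7)
            row = comparisons[(comparisons["mark"] == mark)
                              & (comparisons["comparison"] == comparison)]
            p = float(row["p_value"].iloc[0]) if len(row) else float("nan")
            ax.set_title(f"{mark} {comparison}\np = {p:.2e}", fontsize=8)
    fig.tight_layout()
    png = outdir / "violin_panels.png"
    fig.savefig(png, dpi=150)
    print(f"comparison table -> {outdir}/comparisons.tsv; panels -> {png}")
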