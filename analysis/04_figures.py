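#!/usr/bin/env python
"""Figures for the simulated experiment (written under scratch/).

Box plots of the maximum osteotomy deviation by method and phantom
variant, and by case within the iliac-crest region.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
trials = pd.read_csv(ROOT / "results" / "experiment" / "trials.csv")
ok = trials[trials.status == "ok"]
OUT = ROOT / "scratch" / "figures"
OUT.mkdir(parents=True, exist_ok=True)

fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
for ax, phantom in zip(axes, ["conventional", "realistic"]):
    sub = ok[ok.phantom == phantom]
    data = [sub.loc[sub.method == m, "mod_mm"] for m in ("freehand", "smartphone", "hololens")]
    ax.boxplot(data, tick_labels=["freehand", "smartphone", "hololens"])
    ax.set_title(f"{phantom} phantom")
    ax.set_ylabel("maximum osteotomy deviation (mm)")
    ax.set_yscale("log")
fig.tight_layout()
fig.savefig(OUT / "mod_by_method.png", dpi=150)

fig, ax = plt.subplots(figsize=(6, 4))
sub = ok[ok.region == "C"]
data = [sub.loc[sub.case_id == c, "mod_mm"] for c in range(1, 7)]
ax.boxplot(data, tick_labels=[f"case {c}" for c in range(1, 7)])
ax.set_ylabel("MOD (mm), iliac-crest region")
ax.set_yscale("log")
fig.tight_layout()
fig.savefig(OUT / "mod_by_case_C.png", dpi=150)

print(f"figures written to {OUT}")
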