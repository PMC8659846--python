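#!/usr/bin/env python
"""Nonparametric analysis of the simulated trial table.

Reproduces the analysis structure of the study: the five-number summary
table split by phantom, method, and region; Kruskal-Wallis tests for the
method effect, the per-region case effect, and the phantom effect per
method; Dunn's post-hoc pairwise comparisons for the method effect.
"""

import json
from pathlib import Path

import pandas as pd

from psiplace.pipeline import analyze, report
from psiplace.stats import format_p

RESULTS = Path(__file__).resolve().parent.parent / "results"
trials = pd.read_csv(RESULTS / "experiment" / "trials.csv")

summary = report(trials)
print("maximum osteotomy deviation (mm), five-number summary:")
print(summary.round(2).to_string())

tests = analyze(trials)

kw = tests["methods"]["kruskal_wallis"]
print(f"\nmethod effect: H({kw['df']}) = {kw['H']:.2f}, {format_p(kw['p'])}")
for d in tests["methods"]["dunn"]:
    print(f"  Dunn {d['pair'][0]} vs {d['pair'][1]}: z = {d['z']:.2f}, "
          f"{format_p(d['p'])}")

for region in ("C", "S"):
    t = tests[f"cases_{region}"]
    if t:
        kw = t["kruskal_wallis"]
        print(f"case effect in {region}: H({kw['df']}) = {kw['H']:.2f}, "
              f"{format_p(kw['p'])}")

print("phantom effect (conventional vs soft-tissue) per method:")
for method, t in tests["phantoms_by_method"].items():
    if t:
        kw = t["kruskal_wallis"]
        print(f"  {method}: H({kw['df']}) = {kw['H']:.2f}, {format_p(kw['p'])}")

out = RESULTS / "statistics"
out.mkdir(parents=True, exist_ok=True)
summary.to_csv(out / "summary_table.csv")
(out / "tests.json").write_text(json.dumps(tests, indent=2))
print(f"\nwritten: {out}/summary_table.csv, {out}/tests.json")
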