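#!/usr/bin/env python
"""Recover the published-style inhibition table from the synthetic assays.

Runs the full pipeline (classification, branch-specific fits, competition
corrections) on the datasets written by 01_simulate_assays.py and writes
results/inhibition_report.csv in bench units, mirroring the published table
layout: Ki (nM), kon (10^3 M^-1 s^-1), koff (10^-3 s^-1), with "n.d." for
rate constants that linear progress curves cannot determine.
"""

import pathlib

import pandas as pd

import covkin as ck
from covkin.pipeline import REPORT_COLUMNS, result_to_report_row

DATA = pathlib.Path("results/datasets")
conditions = ck.AssayConditions()

rows = []
for compound, stem in [("slow-binder (Gü1303-like)", "slow_binding"),
                       ("tight-binder (Gü2602-like)", "tight_binding")]:
    curves, meta = ck.simulate.read_curves_csv(DATA / f"{stem}.csv")
    res = ck.analyze_inhibition(curves, conditions)
    rows.append(result_to_report_row(compound, res))
    print(f"{compound}: {res.kinetics_class.label}")
    print(f"  Ki = {res.ki * 1e9:.3f} nM (ground truth {meta['ki_nM']:.3f})")
    if isinstance(res.kon, float):
        print(f"  kon = {res.kon / 1e3:.1f} x10^3 M^-1 s^-1, "
              f"koff = {res.koff * 1e3:.4f} x10^-3 s^-1 "
              f"(intercept diagnostic "
              f"{res.diagnostics['koff_intercept'] * 1e3:.4f} x10^-3 s^-1)")
    else:
        print(f"  kon = {res.kon}; koff = {res.koff}")

report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
out = pathlib.Path("results/inhibition_report.csv")
report.to_csv(out, index=False)
print(f"wrote {out}")
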