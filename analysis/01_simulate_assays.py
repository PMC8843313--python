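#!/usr/bin/env python
"""Generate the reference synthetic assay datasets used by the later stages.

Writes, under results/datasets/:
  - mm_rates.csv            noiseless Michaelis-Menten initial rates (0-100 µM)
  - titration.csv           noiseless E-64-style active-site titration
  - slow_binding.csv        ODE progress curves, slow-binding ground truth
                            (Ki 0.91 nM, kon 527e3 M^-1 s^-1, koff 0.48e-3 s^-1)
  - tight_binding.csv       ODE progress curves, fast/tight-binding ground
                            truth (Ki 0.013 nM; rate constants synthetic)
Each progress-curve CSV carries a .meta.json sidecar with the ground truth.
"""

import pathlib

import numpy as np

import covkin as ck

OUT = pathlib.Path("results/datasets")
OUT.mkdir(parents=True, exist_ok=True)

conditions = ck.AssayConditions()

mm = ck.simulate_mm_rates(17.4, 1.0, [2, 5, 10, 20, 40, 60, 80, 100])
mm.to_csv(OUT / "mm_rates.csv", index=False)
print(f"Michaelis-Menten table: {len(mm)} rates, Km ground truth 17.4 µM")

tit = ck.simulate_titration(0.42, np.linspace(0.0, 0.8, 9))
tit.to_csv(OUT / "titration.csv", index=False)
print("titration table: endpoint ground truth 0.42 nM")

for stem, params, grid in [
    ("slow_binding", ck.GU1303_LIKE, ck.DEFAULT_SLOW_GRID_NM),
    ("tight_binding", ck.GU2602_LIKE, ck.DEFAULT_TIGHT_GRID_NM),
]:
    curves = ck.simulate_progress_curves(params, conditions, grid)
    meta = {"ki_nM": params.ki * 1e9, "kon_Msi": params.kon,
            "koff_si": params.koff, "inhibitor_grid_nM": list(grid),
            "noise_sd": 0.0}
    ck.simulate.write_curves_csv(curves, OUT / f"{stem}.csv", metadata=meta)
    print(f"{stem}: {len(curves)} curves over {grid} nM")
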