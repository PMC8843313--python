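#!/usr/bin/env python
"""Qualitative suppression of zymogen autoactivation by active-site inhibitors.

Simulates the bimolecular autocatalytic conversion pro -> mature over 4 h for
a grid of inhibitor affinities at fixed inhibitor concentration, showing that
tighter binding of the activating species monotonically suppresses zymogen
conversion.  Writes results/autoactivation_suppression.csv.
"""

import pathlib

import numpy as np
import pandas as pd

import covkin as ck

K_ACT = 1e3        # bimolecular activation rate, M^-1 s^-1 (free parameter)
PRO = 1e-6         # zymogen load, M
SEED_ACTIVE = 1e-8 # 1% mature enzyme to nucleate the autocatalysis
INHIBITOR = 2e-6   # inhibitor concentration, M

rows = []
for ki_nm in [np.inf, 1000.0, 100.0, 10.0, 1.0, 0.1]:
    if np.isinf(ki_nm):
        inhib, conc = None, 0.0
    else:
        ki = ki_nm * 1e-9
        inhib, conc = ck.RateConstants(ki=ki, kon=1e6), INHIBITOR
    traj = ck.simulate_zymogen_activation(K_ACT, PRO, SEED_ACTIVE,
                                          inhibitor=inhib, inhibitor_conc=conc)
    conv = traj["mature"].iloc[-1] / (PRO + SEED_ACTIVE)
    rows.append({"ki_nM": ki_nm, "inhibitor_uM": conc * 1e6,
                 "conversion_4h": conv})
    label = "uninhibited" if inhib is None else f"Ki = {ki_nm:g} nM"
    print(f"{label:>14s}: {100 * conv:5.1f}% converted after 4 h")

out = pathlib.Path("results/autoactivation_suppression.csv")
out.parent.mkdir(exist_ok=True)
pd.DataFrame(rows).to_csv(out, index=False)
print(f"wrote {out}\n(conversion decreases monotonically with tighter Ki)")
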