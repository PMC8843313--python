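# covkin

Kinetic and structural analysis of covalent-reversible enzyme inhibitors,
built around the two workhorse experiments of cathepsin K drug discovery:
continuous fluorogenic progress-curve assays and protein–ligand crystal
structure comparison. It is aimed at enzymologists characterising
slow-binding and tight-binding inhibitors (nitrile/cyanohydrazide warheads on
cysteine proteases being the motivating case) who want the full analysis
chain — and a mechanistic simulator to prove the chain recovers known
constants before trusting it with real data.

## What it computes

For a one-step covalent-reversible mechanism E + I ⇌ EI (kon, koff,
K_i = koff/kon) competing with substrate ([S], K_m):

- **Slow-binding branch** — fits each curved progress plot to
  P(t) = v_s·t + (v_i − v_s)(1 − e^(−k_obs·t))/k_obs + d, regresses
  k_obs = k′on·[I] + koff, fits the dose–response
  v_s/v₀ = 1/(1 + [I]/K_i′), and applies the competition corrections
  kon = k′on·(1 + [S]/K_m), K_i = K_i′/(1 + [S]/K_m).
- **Fast/tight-binding branch** — fits steady-state velocities of linear
  progress plots with the Morrison depletion-corrected equation (E₀ fixed
  from active-site titration), then Cheng–Prusoff; kon/koff are reported as
  "n.d." because linear curves carry no rate information.
- **Support fits** — Michaelis–Menten K_m/Vmax, E-64-style active-site
  titration endpoints, and automatic slow- vs fast-binding classification by
  per-curve AICc model comparison.
- **Mechanistic simulator** — integrates the full E/ES/EI/S/P mass-action
  network (plus Michaelis–Menten, titration and zymogen-autoactivation
  generators) with seeded noise, so every estimator is validated by
  parameter recovery.
- **Structure module** — distance-based H-bond candidates (3.3 Å) and
  hydrophobic-carbon contacts (4.2 Å) with covalent-adduct exclusion, Kabsch
  backbone superposition r.m.s.d., in-frame ligand r.m.s.d., and ligand
  B-factor profiling for PDB models.

See `docs/methods.md` for the model, assumptions, defaults and limitations.

## Worked example

```python
import covkin as ck

cond = ck.AssayConditions()          # S=20 µM, Km=17.4 µM, E0=0.42 nM, 40 min
curves = ck.simulate_progress_curves(ck.GU1303_LIKE, cond)   # noiseless
result = ck.analyze_inhibition(curves, cond)
print(result.kinetics_class.label)
print(f"Ki  = {result.ki * 1e9:.3f} nM")
print(f"kon = {result.kon / 1e3:.1f} x10^3 M^-1 s^-1")
print(f"koff= {result.koff * 1e3:.4f} x10^-3 s^-1")
```

prints

```
slow_binding
Ki  = 0.950 nM
kon = 526.0 x10^3 M^-1 s^-1
koff= 0.5000 x10^-3 s^-1
```

The simulator's ground truth was K_i = 0.911 nM, kon = 527×10³ M⁻¹s⁻¹,
koff = 0.48×10⁻³ s⁻¹: the whole chain (ODE assay → per-curve fits →
secondary regressions → corrections) recovers each constant to within ~4%,
the residual bias coming from real tight-binding inhibitor depletion that
the classical dose–response analysis ignores (see `docs/methods.md`).

The same workflow is scripted as a narrative analysis under `analysis/`
(run from the repository root, in order): `01_simulate_assays.py` writes the
reference synthetic datasets, `02_table1_recovery.py` recovers the
inhibition-table constants for both kinetic classes,
`03_classification_robustness.py` scores the classifier under assay noise,
`04_autoactivation.py` demonstrates suppression of zymogen autoactivation,
and `05_structure_criteria.py` exercises the structural criteria on a
synthetic toy complex. Outputs land in `results/`.

A CLI mirrors the library for shell use:

```
covkin simulate --ki-nm 0.91 --kon 527000 --seed 7 --out runs/sim
covkin analyze runs/sim/curves.csv --compound-id demo --out runs/demo
covkin superpose a.pdb b.pdb --ligand LIG
```

## Layout

```
src/covkin/          library: kinetics, simulate, fitting, pipeline, structure, cli
analysis/            numbered narrative drivers (01..05)
tests/               pytest suite incl. property tests and toy-structure oracles
scripts/acceptance.py  headline-number reproduction
docs/methods.md      model, assumptions, defaults, limitations
```
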