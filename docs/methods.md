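# Methods

## The kinetic model

`covkin` analyses competitive, covalent-reversible inhibition of a
Michaelis–Menten enzyme, the mechanism of nitrile-type warheads binding the
catalytic cysteine of cathepsin K. The mass-action network is

```
E + S  ⇌  ES   (k1, k−1)        substrate binding
ES     →  E + P (kcat)          turnover (fluorescent product)
E + I  ⇌  EI   (kon, koff)      one-step reversible covalent inhibition
```

with K_m = (k−1 + kcat)/k1 and K_i = koff/kon. Because the inhibitor competes
with substrate for free enzyme, all quantities measured in the presence of
substrate are *apparent*: K_i′ = K_i·(1 + [S]/K_m) and k′on = kon/(1 + [S]/K_m).

Two regimes are handled by separate analysis branches:

**Slow binding** — when 1/(k′on[I] + koff) is comparable to the assay duration,
product formation follows

P(t) = v_s·t + (v_i − v_s)(1 − e^(−k_obs·t))/k_obs + d,

with initial velocity v_i, steady-state velocity v_s and
k_obs = k′on·[I] + koff. The branch fits each curve for k_obs and v_s,
regresses k_obs on [I] (slope k′on, intercept), fits the classical
dose–response v_s/v_0 = 1/(1 + [I]/K_i′), and applies the substrate-competition
corrections kon = k′on(1 + [S]/K_m) and K_i = K_i′/(1 + [S]/K_m).

**Fast/tight binding** — when binding equilibrates within one sampling
interval the curves are linear, k_obs is not measurable, and sub-nanomolar
affinity at ~0.4 nM enzyme puts the assay in the tight-binding regime where
free inhibitor is depleted by complex formation. Steady-state velocities are
fitted with the Morrison equation

v/v₀ = 1 − [(E₀ + I + K_i′) − √((E₀ + I + K_i′)² − 4·E₀·I)]/(2·E₀),

with E₀ fixed (known independently from active-site titration), followed by
the same Cheng–Prusoff correction. kon and koff are reported as "n.d."
(explicit absent-with-reason values): linear progress curves carry no rate
information.

### Reporting koff on the slow branch

Under the standard assay conditions the slow-binding reference inhibitor is
itself mildly tight-binding (K_i′ ≈ 2 nM against E₀ = 0.42 nM): up to ~0.4 nM
of inhibitor is sequestered in EI at steady state, which biases the raw
k_obs-vs-[I] intercept low by 7–15% while leaving the slope almost untouched.
The pipeline therefore reports koff = kon·K_i — the equilibrium identity that
the three constants of a one-step mechanism must satisfy, and the only way
the reported triple can be self-consistent — and keeps the raw intercept
(with its standard error) as a diagnostic (`diagnostics["koff_intercept"]`).

## Classification of kinetics

Per inhibited curve, a straight line (2 parameters) and the progress equation
(4 parameters) are compared by small-sample-corrected AIC. A curve counts as
slow-binding evidence only if

1. the exponential model is preferred by ΔAICc > 10, and
2. the fitted transient develops within the assay window
   (k_obs · duration ≥ 1).

Without the second condition, any slow systematic drift — mild substrate
depletion curves every real progress plot — would masquerade as slow-binding
kinetics. Residual sums of squares entering the AICc are floored at
n·(10⁻³ × signal range)²: the comparison assumes the plate reader cannot
resolve deviations below 0.1% of range, so solver-precision residuals in
noiseless synthetic data carry no evidence. The verdict follows the majority
of inhibited curves and is withheld on a tie.

## Synthetic-data generator

The generator's defaults are the standard fluorogenic cathepsin K assay:
[S] = 20 µM Cbz-Gly-Pro-Arg-AMC, K_m = 17.4 µM, E₀ = 0.42 nM, 40 min
monitored every 10 s; inhibitor grids 0–100 nM (slow, two-fold steps from
6.25 nM) and 0–2 nM (tight). Choices the assay itself does not pin down:

- **kcat = 2 s⁻¹** — typical cathepsin K turnover; keeps substrate depletion
  at ≈5% over 40 min so initial-rate assumptions hold (a warning is emitted
  beyond 10%).
- **k1 = 10⁷ M⁻¹s⁻¹** — diffusion-limited substrate association; only K_m is
  constrained, and with kcat ≪ k−1 the steady-state and equilibrium K_m
  coincide to ~1%.
- **Fast-binder rate constants** — only K_i = 0.013 nM is constrained for the
  tight-binding reference; kon = 10¹⁰ M⁻¹s⁻¹ (with koff = K_i·kon) is a
  synthetic choice that completes equilibration within one sampling interval,
  as the linear experimental curves require. It is a label for curve shape,
  not a physical estimate.
- **Readout** — gain 10⁹ AU/M (≈1000 AU full scale), additive i.i.d. Gaussian
  noise, default sd 0.5% of full scale, seed mandatory whenever sd > 0.

Integration uses LSODA with rtol 10⁻⁸ and atol 10⁻⁸ × the smallest initial
pool, so "noiseless" runs are deterministic to far below fitting tolerances;
enzyme and substrate+product conservation are checked to 10⁻⁶ relative on
every run. The generator emulates curve shape and additive noise only: it
does not model inner-filter effects, photobleaching, pipetting error,
autofluorescence drift, or glycosaminoglycan rate enhancement. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated mechanism, not robustness to every real-world
artefact.

The zymogen-autoactivation model (d[pro]/dt = −k_act·[pro]·[mat_free], with
mat_free reduced by Morrison equilibrium binding of the inhibitor) is
qualitative: k_act, the zymogen load and the nucleating amount of mature
enzyme are free parameters (defaults 10³ M⁻¹s⁻¹, 1 µM, 1%), and the model
claims only the monotone suppression of conversion with tighter K_i, not any
particular conversion percentage.

## Numerical choices

- Progress-equation evaluation switches to its series expansion for
  k_obs·t < 10⁻⁸ (the k_obs → 0 limit is d + v_i·t, not a division error).
- Progress-fit initialisation is derivative-free: v_i from the slope of the
  first 10% of points, v_s and the asymptote from the last 20%, d from the
  first point, k_obs from a log-linear fit of the transient deficit below
  the asymptote.
- All rate/affinity parameters are bounded positive during optimisation
  (lmfit least squares); standard errors come from the Gauss–Newton
  covariance approximation.
- k_obs-vs-[I] and titration analyses are ordinary least squares; a fitted
  negative intercept is reported with a warning (koff is physically ≥ 0),
  and two-point lines are exact interpolations with undefined SEs, flagged.
- Titration endpoint: points below 10% residual activity are excluded from
  the linear segment (curvature near the stoichiometric endpoint); the
  endpoint is the x-intercept of the remaining line.
- Morrison discriminant values that go (numerically) negative are clamped to
  zero with a warning; the fraction is clipped to [0, 1].
- Dose-response v₀ comes from the [I] = 0 curve fitted with the same model
  family, preferring the straight line when both fit equally well.

## Structural criteria

Contacts use the crystallographers' distance-only definitions appropriate
for models without hydrogens: H-bond candidates are N/O/S–N/O/S pairs within
3.3 Å; nonpolar contacts are pairs of hydrophobic carbons (every covalent
neighbour C or H, which excludes carbonyl/amide carbons) within 4.2 Å.
Covalent bonds are inferred by d < r_cov(a) + r_cov(b) + 0.4 Å, and
covalently bonded pairs — in particular a warhead–cysteine adduct linkage —
are excluded from contact lists. No angle terms are applied.

Superposition is a closed-form Kabsch/SVD Procrustes fit over backbone
N, CA, C atoms (O excluded; "backbone" is ambiguous by one atom, worth a few
hundredths of an Å) matched by chain and residue number; ligand r.m.s.d. is
computed over name-matched heavy atoms *after* applying the protein backbone
superposition, with no refit on the ligand. PDB parsing (gemmi) takes the
first model and resolves altlocs to the highest-occupancy conformer.

## Problem sizes

Reference analyses use 6 (slow) and 7 (tight) progress curves of 241 points,
8-point Michaelis–Menten tables, 9-point titrations, 20 noise replicates per
compound for classification robustness, and ≤10-atom toys for the
superposition oracle — sizes at which every stage's independent oracle
(closed forms, brute-force orientation search) is cheap to evaluate.

## Known limitations

One-step binding only (no induced-fit/two-step slow binding, no irreversible
inactivation); per-curve fitting with secondary analyses rather than global
multi-curve fits; classical dose-response (not Morrison) on the slow branch,
matching the standard workflow but contributing a few percent of bias under
tight-binding conditions; distance-only interaction criteria; PDB format
only (no mmCIF).
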