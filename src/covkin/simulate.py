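"""Mechanistic synthetic-data generators for the continuous fluorogenic assay.

The progress-curve generator integrates the full mass-action network

    E + S <=> ES   (k1, k_-1)      substrate binding
    ES -> E + P    (kcat)          turnover (fluorescent product)
    E + I <=> EI   (kon, koff)     one-step covalent-reversible inhibition

so that every approximation made downstream (steady-state velocities, the
single-exponential progress equation, the Morrison depletion correction) can
be tested against data in which none of those approximations was assumed.
Signal = gain*[P] + offset + additive Gaussian noise; identical seeds give
bit-identical output.

Also provided: Michaelis-Menten initial-rate tables, stoichiometric
irreversible active-site titration tables, and a qualitative bimolecular
zymogen-autoactivation model in which the activating (mature/intermediate)
species is sequestered by equilibrium inhibitor binding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import json
import pathlib
import warnings

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (
    AssayConditions,
    RateConstants,
    morrison_fraction,
    michaelis_menten_rate,
)

__all__ = [
    "MechanismParams",
    "NoiseModel",
    "ProgressCurve",
    "SimulationError",
    "SubstrateDepletionWarning",
    "GU1303_LIKE",
    "GU2602_LIKE",
    "DEFAULT_SLOW_GRID_NM",
    "DEFAULT_TIGHT_GRID_NM",
    "simulate_progress_curves",
    "species_trajectories",
    "simulate_mm_rates",
    "simulate_titration",
    "simulate_zymogen_activation",
    "curves_to_frame",
    "frame_to_curves",
    "write_curves_csv",
    "read_curves_csv",
]

#: default inhibitor grids (nM).  The slow-binding grid spans the assay's
#: stated 0-100 nM range in two-fold steps; the tight-binding grid brackets
#: the sub-nanomolar apparent Ki while spanning the enzyme concentration.
DEFAULT_SLOW_GRID_NM = (0.0, 6.25, 12.5, 25.0, 50.0, 100.0)
DEFAULT_TIGHT_GRID_NM = (0.0, 0.1, 0.2, 0.4, 0.8, 1.2, 2.0)


class SimulationError(RuntimeError):
    """ODE integration failed; message echoes the offending parameters."""


class SubstrateDepletionWarning(UserWarning):
    """More than 10% of substrate consumed: initial-rate assumptions at risk."""


@dataclass(frozen=True)
class MechanismParams:
    """Ground-truth microscopic constants of a simulated enzyme/inhibitor pair.

    ki (M), kon (1/(M*s)), koff (1/s) obey koff = ki*kon; km (M) and kcat
    (1/s) describe the substrate, with diffusion-limited substrate association
    k1 (default 1e7 1/(M*s)) and k_-1 = k1*km - kcat >= 0.
    """

    ki: float
    kon: float
    koff: float
    km: float = 17.4e-6
    kcat: float = 2.0
    k1: float = 1e7

    def __post_init__(self) -> None:
        RateConstants(kon=self.kon, koff=self.koff, ki=self.ki)  # consistency
        if self.km <= 0 or self.kcat <= 0 or self.k1 <= 0:
            raise ValueError("km, kcat, k1 must be strictly positive")
        if self.k_minus1 < 0:
            raise ValueError("k1*km must be >= kcat (k_-1 would be negative)")

    @property
    def k_minus1(self) -> float:
        return self.k1 * self.km - self.kcat

    @classmethod
    def from_rates(cls, rates: RateConstants, **kwargs) -> "MechanismParams":
        return cls(ki=rates.ki, kon=rates.kon, koff=rates.koff, **kwargs)


#: slow-binding reference inhibitor (azadipeptide-nitrile-like):
#: Ki = koff/kon = 0.48e-3 / 527e3 M
GU1303_LIKE = MechanismParams(ki=0.48e-3 / 527e3, kon=527e3, koff=0.48e-3)

#: fast/tight-binding reference inhibitor (3-cyano-3-aza-beta-amino-acid-like).
#: Only Ki = 0.013 nM is constrained; the individual rate constants are a
#: synthetic choice made fast enough that binding equilibrates within one
#: sampling interval, giving linear progress curves.
GU2602_LIKE = MechanismParams(ki=0.013e-9, kon=1e10, koff=0.013e-9 * 1e10)


@dataclass(frozen=True)
class NoiseModel:
    """Fluorescence readout model: signal = gain*[P] + offset + N(0, sd^2).

    gain in AU/M of product, offset and sd in AU.  The default gain maps the
    ~1 µM of product formed in an uninhibited 40-min run to ~1000 AU.
    """

    gain: float = 1e9
    offset: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be strictly positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class ProgressCurve:
    """One assay time-series at a fixed inhibitor concentration (molar)."""

    inhibitor_conc: float
    times: np.ndarray
    signal: np.ndarray
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape:
            raise ValueError("times and signal must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)


def _rhs(t, y, k1, km1, kcat, kon, koff, itot):
    e, es, ei, s, p = y
    i_free = itot - ei
    v_bind = k1 * e * s - km1 * es
    v_cat = kcat * es
    v_inh = kon * e * i_free - koff * ei
    return (
        -v_bind + v_cat - v_inh,
        v_bind - v_cat,
        v_inh,
        -v_bind,
        v_cat,
    )


def _integrate(params: MechanismParams, cond: AssayConditions, itot: float,
               rtol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the five-species network; returns (times, [P] trajectory)."""
    t = cond.times()
    y0 = (cond.enzyme_conc, 0.0, 0.0, cond.substrate_conc, 0.0)
    # atol well below the enzyme scale so nM-level species stay accurate
    atol = min(cond.enzyme_conc, cond.substrate_conc) * 1e-8
    sol = solve_ivp(
        _rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA",
        rtol=rtol, atol=atol,
        args=(params.k1, params.k_minus1, params.kcat, params.kon, params.koff, itot),
    )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed ({sol.message}); params={params}, "
            f"conditions={cond}, [I]={itot:g} M"
        )
    e, es, ei, s, p = sol.y
    etot = e + es + ei
    mass = s + p + es
    if (np.max(np.abs(etot - cond.enzyme_conc)) > 1e-6 * cond.enzyme_conc
            or np.max(np.abs(mass - cond.substrate_conc)) > 1e-6 * cond.substrate_conc):
        raise SimulationError("mass conservation violated beyond 1e-6 relative")
    if s[-1] < 0.9 * cond.substrate_conc and itot == 0.0:
        warnings.warn(
            f"{100 * (1 - s[-1] / cond.substrate_conc):.1f}% substrate consumed; "
            "initial-rate assumptions may not hold",
            SubstrateDepletionWarning,
        )
    return sol.t, p


def species_trajectories(
    params: MechanismParams,
    cond: AssayConditions | None = None,
    inhibitor_conc: float = 0.0,
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Full species trajectories E, ES, EI, S, P (molar) for one condition.

    ``inhibitor_conc`` in molar.  Exposes the raw integration so conservation
    laws and steady-state approximations can be examined directly.
    """
    if cond is None:
        cond = AssayConditions(km=params.km)
    t = cond.times()
    y0 = (cond.enzyme_conc, 0.0, 0.0, cond.substrate_conc, 0.0)
    atol = min(cond.enzyme_conc, cond.substrate_conc) * 1e-8
    sol = solve_ivp(
        _rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA",
        rtol=rtol, atol=atol,
        args=(params.k1, params.k_minus1, params.kcat, params.kon, params.koff,
              inhibitor_conc),
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed ({sol.message})")
    return pd.DataFrame({
        "time_s": sol.t, "E": sol.y[0], "ES": sol.y[1], "EI": sol.y[2],
        "S": sol.y[3], "P": sol.y[4],
    })


def simulate_progress_curves(
    params: MechanismParams,
    cond: AssayConditions | None = None,
    inhibitor_concs=DEFAULT_SLOW_GRID_NM,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    *,
    concs_in_nM: bool = True,
    rtol: float = 1e-8,
) -> list[ProgressCurve]:
    """Simulate one progress curve per inhibitor concentration.

    ``inhibitor_concs`` is in nM by default (the bench unit); pass
    ``concs_in_nM=False`` for molar.  ``seed`` feeds a fresh PRNG so identical
    seeds give bit-identical signals; it is required whenever noise.sd > 0.
    """
    if cond is None:
        cond = AssayConditions(km=params.km)
    if noise.sd > 0 and seed is None:
        raise ValueError("seed is required when noise.sd > 0")
    rng = np.random.default_rng(seed)
    curves = []
    for c in inhibitor_concs:
        itot = float(c) * (1e-9 if concs_in_nM else 1.0)
        if itot < 0:
            raise ValueError("inhibitor concentrations must be non-negative")
        t, p = _integrate(params, cond, itot, rtol=rtol)
        sig = noise.gain * p + noise.offset
        if noise.sd > 0:
            sig = sig + rng.normal(0.0, noise.sd, size=sig.shape)
        curves.append(ProgressCurve(itot, t, sig, noise_sd=noise.sd, seed=seed))
    return curves


def simulate_mm_rates(
    km: float,
    vmax: float,
    substrate_concs,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Initial-rate table v([S]) = Vmax*S/(Km+S) + N(0, sd^2).

    Units are the caller's (km and substrate_concs must agree); returns
    columns substrate_conc, rate.
    """
    s = np.asarray(substrate_concs, dtype=float)
    v = michaelis_menten_rate(s, vmax, km)
    if noise_sd > 0:
        if seed is None:
            raise ValueError("seed is required when noise_sd > 0")
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, size=v.shape)
    return pd.DataFrame({"substrate_conc": s, "rate": v})


def simulate_titration(
    enzyme_true: float,
    titrant_concs,
    noise_sd: float = 0.0,
    seed: int | None = None,
    v0: float = 1.0,
) -> pd.DataFrame:
    """Irreversible stoichiometric active-site titration (E-64-style).

    Residual activity = max(0, 1 - [titrant]/E_true) * v0 + noise; the linear
    segment's abscissa intercept equals the active-enzyme concentration.
    Returns columns titrant_conc, activity.
    """
    if enzyme_true <= 0:
        raise ValueError("enzyme_true must be strictly positive")
    c = np.asarray(titrant_concs, dtype=float)
    a = np.clip(1.0 - c / enzyme_true, 0.0, None) * v0
    if noise_sd > 0:
        if seed is None:
            raise ValueError("seed is required when noise_sd > 0")
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=a.shape)
    return pd.DataFrame({"titrant_conc": c, "activity": a})


def simulate_zymogen_activation(
    k_act: float,
    pro_conc: float,
    seed_active: float,
    inhibitor: RateConstants | None = None,
    inhibitor_conc: float = 0.0,
    times=None,
    substrate_conc: float = 0.0,
    km: float = 17.4e-6,
) -> pd.DataFrame:
    """Bimolecular autocatalytic zymogen processing, optionally suppressed.

    d[pro]/dt = -k_act*[pro]*[mat_free];  d[mat]/dt = +k_act*[pro]*[mat_free]

    where mat_free is the mature (activating) species not sequestered by the
    inhibitor, computed at each instant from the Morrison equilibrium-binding
    fraction with apparent Ki' = Ki*(1+[S]/Km).  Qualitative model: the rate
    constant and the identity of the activating species are free parameters.
    Returns columns time_s, pro, mature; pro+mature is conserved.
    """
    if k_act <= 0 or pro_conc < 0 or seed_active < 0 or inhibitor_conc < 0:
        raise ValueError("rates and concentrations must be non-negative (k_act > 0)")
    if times is None:
        times = np.linspace(0.0, 4 * 3600.0, 97)
    times = np.asarray(times, dtype=float)

    if inhibitor is not None and inhibitor_conc > 0:
        ki_app = inhibitor.ki * (1.0 + substrate_conc / km)
    else:
        ki_app = None

    def rhs(t, y):
        pro, mat = y
        if ki_app is not None and mat > 0:
            free = mat * morrison_fraction(mat, inhibitor_conc, ki_app)
        else:
            free = mat
        v = k_act * pro * free
        return (-v, v)

    total = pro_conc + seed_active
    sol = solve_ivp(rhs, (times[0], times[-1]), (pro_conc, seed_active),
                    t_eval=times, method="LSODA", rtol=1e-8, atol=total * 1e-10)
    if not sol.success:
        raise SimulationError(f"autoactivation integration failed: {sol.message}")
    return pd.DataFrame({"time_s": sol.t, "pro": sol.y[0], "mature": sol.y[1]})


# ---------------------------------------------------------------------------
# CSV interchange (long format keyed by inhibitor_nM) + metadata sidecar

def curves_to_frame(curves: list[ProgressCurve]) -> pd.DataFrame:
    frames = [
        pd.DataFrame({
            "inhibitor_nM": c.inhibitor_conc * 1e9,
            "time_s": c.times,
            "signal_au": c.signal,
        })
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)


def frame_to_curves(df: pd.DataFrame) -> list[ProgressCurve]:
    curves = []
    for conc, grp in df.groupby("inhibitor_nM", sort=True):
        grp = grp.sort_values("time_s")
        curves.append(ProgressCurve(
            float(conc) * 1e-9,
            grp["time_s"].to_numpy(),
            grp["signal_au"].to_numpy(),
        ))
    return curves


def write_curves_csv(curves: list[ProgressCurve], path, metadata: dict | None = None) -> None:
    path = pathlib.Path(path)
    curves_to_frame(curves).to_csv(path, index=False)
    if metadata is not None:
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")


def read_curves_csv(path) -> tuple[list[ProgressCurve], dict | None]:
    path = pathlib.Path(path)
    df = pd.read_csv(path)
    missing = {"inhibitor_nM", "time_s", "signal_au"} - set(df.columns)
    if missing:
        raise ValueError(f"progress-curve CSV missing columns: {sorted(missing)}")
    meta = None
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return frame_to_curves(df), meta
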