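"""Closed-form rate equations for competitive covalent-reversible inhibition.

All functions are pure and operate on SI-style internal units: concentrations
in molar, times in seconds, first-order rate constants in 1/s and second-order
rate constants in 1/(M*s).  I/O layers convert from the assay units commonly
used at the bench (µM substrate, nM enzyme and inhibitor).

The model is one-step reversible binding of an inhibitor I to the free enzyme
E (E + I <=> EI, rates kon/koff) in competition with a Michaelis-Menten
substrate.  Substrate competition inflates the measured (apparent) inhibition
constant by the factor (1 + [S]/Km); the same factor deflates the apparent
association rate constant.  Slow-binding inhibitors produce curved progress
plots whose approach to steady state is a single exponential with observed
rate constant

    k_obs = k'on * [I] + koff,        k'on = kon / (1 + [S]/Km).

Tight-binding inhibitors (K_i comparable to enzyme concentration) require the
Morrison depletion-corrected velocity expression instead of the classical
dose-response hyperbola.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np

__all__ = [
    "AssayConditions",
    "ProgressParams",
    "RateConstants",
    "michaelis_menten_rate",
    "progress_signal",
    "kobs_from_inhibitor",
    "steady_state_fraction",
    "morrison_fraction",
    "cheng_prusoff",
    "kon_true",
    "ki_from_rates",
    "competition_factor",
]

#: below this value of k_obs*t the exponential term of the progress equation
#: is evaluated by series expansion to avoid catastrophic cancellation
_KOBS_T_SERIES_THRESHOLD = 1e-8


@dataclass(frozen=True)
class AssayConditions:
    """Fluorogenic continuous-assay layout.

    Defaults mirror the Cbz-Gly-Pro-Arg-AMC cathepsin K assay: 20 µM substrate
    against Km = 17.4 µM, 0.42 nM enzyme, 40 min monitored at 10 s intervals.
    Stored in molar / seconds.
    """

    substrate_conc: float = 20e-6
    km: float = 17.4e-6
    enzyme_conc: float = 0.42e-9
    duration: float = 2400.0
    sampling_interval: float = 10.0

    def __post_init__(self) -> None:
        for name in ("substrate_conc", "km", "enzyme_conc", "duration", "sampling_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"AssayConditions.{name} must be strictly positive")
        if self.duration <= self.sampling_interval:
            raise ValueError("duration must exceed sampling_interval")

    @property
    def factor(self) -> float:
        """Substrate-competition factor (1 + [S]/Km)."""
        return competition_factor(self.substrate_conc, self.km)

    def times(self) -> np.ndarray:
        """Sampling grid 0..duration inclusive."""
        n = int(round(self.duration / self.sampling_interval))
        return np.arange(n + 1) * self.sampling_interval


@dataclass(frozen=True)
class ProgressParams:
    """Parameters of the slow-binding progress equation.

    vs, vi: steady-state and initial velocities (signal units per second);
    kobs: observed first-order rate constant (1/s); d: signal offset.
    """

    vs: float
    vi: float
    kobs: float
    d: float = 0.0

    def __post_init__(self) -> None:
        if self.kobs < 0:
            raise ValueError("kobs must be non-negative")
        if self.vs < 0 or self.vi < 0:
            raise ValueError("velocities must be non-negative")


@dataclass(frozen=True)
class RateConstants:
    """Microscopic one-step binding constants; ki = koff/kon must hold.

    Any one of the three may be omitted (None) and is filled in from the other
    two; supplying all three asserts consistency to ``rtol``.
    """

    kon: float | None = None
    koff: float | None = None
    ki: float | None = None
    rtol: float = 1e-6

    def __post_init__(self) -> None:
        kon, koff, ki = self.kon, self.koff, self.ki
        given = sum(v is not None for v in (kon, koff, ki))
        if given < 2:
            raise ValueError("need at least two of kon, koff, ki")
        if kon is None:
            kon = koff / ki
        elif koff is None:
            koff = kon * ki
        elif ki is None:
            ki = koff / kon
        else:
            if not math.isclose(ki * kon, koff, rel_tol=self.rtol):
                raise ValueError(
                    f"inconsistent constants: ki*kon={ki * kon:g} vs koff={koff:g}"
                )
        if kon <= 0 or koff < 0 or ki < 0:
            raise ValueError("rate constants must be positive (koff, ki non-negative)")
        object.__setattr__(self, "kon", kon)
        object.__setattr__(self, "koff", koff)
        object.__setattr__(self, "ki", ki)


def competition_factor(substrate_conc: float, km: float) -> float:
    """(1 + [S]/Km), the competitive-substrate correction factor."""
    if km <= 0:
        raise ValueError("km must be strictly positive")
    if substrate_conc < 0:
        raise ValueError("substrate concentration must be non-negative")
    return 1.0 + substrate_conc / km


def michaelis_menten_rate(substrate_conc, vmax, km):
    """Michaelis-Menten initial rate v = Vmax*[S]/(Km+[S])."""
    if km <= 0:
        raise ValueError("km must be strictly positive")
    s = np.asarray(substrate_conc, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be non-negative")
    out = vmax * s / (km + s)
    return out if out.ndim else float(out)


def progress_signal(t, p: ProgressParams):
    """Slow-binding progress equation.

    P(t) = vs*t + (vi - vs) * (1 - exp(-kobs*t)) / kobs + d

    The curve starts with slope vi, relaxes with rate kobs and ends with
    asymptotic slope vs.  For kobs*t -> 0 the analytic limit d + vi*t is used
    (second-order series), so kobs = 0 is not a division error.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    kt = p.kobs * t
    small = kt < _KOBS_T_SERIES_THRESHOLD
    out = np.empty_like(t)
    # series: (1-exp(-kt))/k = t - k t^2/2 + O(k^2 t^3)
    out[small] = p.vi * t[small] - (p.vi - p.vs) * p.kobs * t[small] ** 2 / 2.0
    if np.any(~small):
        tl = t[~small]
        out[~small] = p.vs * tl + (p.vi - p.vs) * (1.0 - np.exp(-p.kobs * tl)) / p.kobs
    out += p.d
    return out if out.ndim else float(out)


def kobs_from_inhibitor(inhibitor_conc, kon_app: float, koff: float):
    """k_obs = k'on*[I] + koff (linear one-step slow-binding relation)."""
    i = np.asarray(inhibitor_conc, dtype=float)
    if np.any(i < 0):
        raise ValueError("inhibitor concentration must be non-negative")
    out = kon_app * i + koff
    return out if out.ndim else float(out)


def steady_state_fraction(inhibitor_conc, ki_app: float):
    """Classical competitive dose-response vs/v0 = 1/(1 + [I]/Ki')."""
    if ki_app <= 0:
        raise ValueError("ki_app must be strictly positive")
    i = np.asarray(inhibitor_conc, dtype=float)
    if np.any(i < 0):
        raise ValueError("inhibitor concentration must be non-negative")
    out = 1.0 / (1.0 + i / ki_app)
    return out if out.ndim else float(out)


def morrison_fraction(enzyme_conc: float, inhibitor_conc, ki_app):
    """Morrison tight-binding velocity fraction v/v0.

    v/v0 = 1 - [ (E0 + I + Ki') - sqrt((E0 + I + Ki')^2 - 4*E0*I) ] / (2*E0)

    accounts for depletion of free inhibitor when [I] is comparable to the
    enzyme concentration E0.  Reduces to the classical hyperbola as E0 -> 0.
    A numerically negative discriminant is clamped to zero with a warning.
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be strictly positive")
    i = np.asarray(inhibitor_conc, dtype=float)
    k = np.asarray(ki_app, dtype=float)
    if np.any(i < 0) or np.any(k < 0):
        raise ValueError("concentrations must be non-negative")
    b = enzyme_conc + i + k
    disc = b * b - 4.0 * enzyme_conc * i
    if np.any(disc < 0):
        warnings.warn("negative Morrison discriminant clamped to zero", RuntimeWarning)
        disc = np.clip(disc, 0.0, None)
    frac = 1.0 - (b - np.sqrt(disc)) / (2.0 * enzyme_conc)
    frac = np.clip(frac, 0.0, 1.0)
    return frac if frac.ndim else float(frac)


def cheng_prusoff(ki_app: float, substrate_conc: float, km: float) -> float:
    """True inhibition constant Ki = Ki' / (1 + [S]/Km)."""
    return ki_app / competition_factor(substrate_conc, km)


def kon_true(kon_app: float, substrate_conc: float, km: float) -> float:
    """True association rate constant kon = k'on * (1 + [S]/Km)."""
    return kon_app * competition_factor(substrate_conc, km)


def ki_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant Ki = koff/kon (molar)."""
    if kon <= 0:
        raise ValueError("kon must be strictly positive")
    if koff < 0:
        raise ValueError("koff must be non-negative")
    return koff / kon
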