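"""End-to-end inhibition analysis: classify, fit, correct, report.

Given a set of progress curves (one uninhibited) and the assay conditions,
the pipeline classifies the kinetics and runs the matching branch:

slow-binding branch
    per-curve progress fits -> k_obs; OLS of k_obs vs [I] -> k'on (slope) and
    the intercept; dose-response of vs/v0 -> Ki'; Cheng-Prusoff -> Ki;
    kon = k'on*(1+[S]/Km).  The reported koff is kon*Ki — the equilibrium
    identity that ties the three constants together (the raw regression
    intercept, which under tight-binding conditions is biased low by
    inhibitor depletion, is kept as a diagnostic).

fast-binding branch
    steady-state slopes -> Morrison tight-binding fit of Ki' with E0 fixed ->
    Cheng-Prusoff -> Ki; kon and koff are not determined from linear progress
    curves and are reported as "n.d." with the reason attached.

Report units follow bench convention: Ki in nM, kon in 10^3 M^-1 s^-1,
koff in 10^-3 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from .kinetics import AssayConditions, cheng_prusoff, kon_true
from .fitting import (
    FitResult,
    KineticsClass,
    classify_progress_kinetics,
    fit_dose_response,
    fit_kobs_linear,
    fit_morrison,
    fit_progress_curve,
    steady_state_velocity,
)

__all__ = ["NotDetermined", "InhibitionResult", "AnalysisError", "analyze_inhibition",
           "result_to_report_row", "REPORT_COLUMNS"]

REPORT_COLUMNS = ["compound_id", "class", "Ki_nM", "Ki_se", "kon_1e3_Msi",
                  "kon_se", "koff_1e-3_si", "koff_se"]


class AnalysisError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class NotDetermined:
    """Explicit absent-with-reason value (the Table-style 'n.d.')."""

    reason: str

    def __bool__(self) -> bool:
        return False

    def __str__(self) -> str:
        return f"n.d. ({self.reason})"


@dataclass(frozen=True)
class InhibitionResult:
    """Table-style summary of one inhibitor's kinetic characterisation.

    ki in M with standard error; kon (1/(M*s)) and koff (1/s) carry values
    only for slow-binding kinetics and are NotDetermined otherwise.
    """

    ki: float
    ki_se: float | None
    kon: float | NotDetermined
    kon_se: float | None
    koff: float | NotDetermined
    koff_se: float | None
    kinetics_class: KineticsClass
    conditions: AssayConditions
    diagnostics: dict

    @property
    def ki_nM(self) -> float:
        return self.ki * 1e9


def _v0_from_uninhibited(curve) -> tuple[float, str]:
    """Uninhibited velocity, fitted with the same model family.

    Both the straight line and the progress equation are tried; the line wins
    unless the exponential model is genuinely supported (an identical-quality
    fit is broken toward fewer parameters).  Returns (v0, model_used).
    """
    fit = fit_progress_curve(curve)
    unident = any("unidentifiable" in w for w in fit.warnings)
    if fit.converged and not unident:
        return fit["vs"], "progress"
    t = np.asarray(curve.times, float)
    y = np.asarray(curve.signal, float)
    return float(np.polyfit(t, y, 1)[0]), "linear"


def analyze_inhibition(curves, cond: AssayConditions,
                       kinetics_class: KineticsClass | None = None) -> InhibitionResult:
    """Full characterisation of one inhibitor from its progress curves.

    ``curves`` must include an uninhibited ([I]=0) curve; ``cond`` supplies
    [S], Km and E0.  The kinetics class is determined automatically unless
    supplied.
    """
    curves = sorted(curves, key=lambda c: c.inhibitor_conc)
    uninhibited = [c for c in curves if c.inhibitor_conc == 0]
    inhibited = [c for c in curves if c.inhibitor_conc > 0]
    if not uninhibited:
        raise AnalysisError("stage=input: an uninhibited ([I]=0) curve is required")
    if len(inhibited) < 2:
        raise AnalysisError("stage=input: need >= 2 inhibited curves")

    if kinetics_class is None:
        kinetics_class = classify_progress_kinetics(inhibited)
    if kinetics_class.label is None:
        raise AnalysisError(
            f"stage=classification: {kinetics_class.diagnostic or 'ambiguous evidence'}")

    diagnostics: dict = {"classification": kinetics_class}

    if kinetics_class.label == "slow_binding":
        v0, v0_model = _v0_from_uninhibited(uninhibited[0])
        if v0_model == "progress":
            # an uninhibited curve is linear; fall back to its straight slope
            t = uninhibited[0].times
            v0 = float(np.polyfit(t, uninhibited[0].signal, 1)[0])
        rows = []
        for c in inhibited:
            fit = fit_progress_curve(c)
            if not fit.converged or any("unidentifiable" in w for w in fit.warnings):
                diagnostics.setdefault("skipped_curves", []).append(
                    (c.inhibitor_conc, fit.warnings))
                continue
            rows.append({"inhibitor_conc": c.inhibitor_conc,
                         "kobs": fit["kobs"], "vs": fit["vs"]})
        if len(rows) < 3:
            raise AnalysisError("stage=progress-fits: fewer than 3 usable k_obs values")
        table = pd.DataFrame(rows)
        lin = fit_kobs_linear(table[["inhibitor_conc", "kobs"]])
        dose = fit_dose_response(pd.DataFrame({
            "inhibitor_conc": table["inhibitor_conc"],
            "fraction": np.clip(table["vs"] / v0, 1e-12, 1.0),
        }))
        if not (lin.converged and dose.converged):
            raise AnalysisError("stage=secondary-fits: regression failed")
        factor = cond.factor
        ki = cheng_prusoff(dose["ki_app"], cond.substrate_conc, cond.km)
        ki_se = (dose.se("ki_app") / factor) if dose.se("ki_app") is not None else None
        kon = kon_true(lin["kon_app"], cond.substrate_conc, cond.km)
        kon_se = (lin.se("kon_app") * factor) if lin.se("kon_app") is not None else None
        # equilibrium identity koff = kon*Ki; SE by first-order propagation
        koff = kon * ki
        koff_se = None
        if ki_se is not None and kon_se is not None:
            koff_se = math.hypot(ki * kon_se, kon * ki_se)
        diagnostics.update({
            "kobs_table": table,
            "kobs_regression": lin,
            "dose_response": dose,
            "koff_intercept": lin["koff"],
            "koff_intercept_se": lin.se("koff"),
            "v0": v0,
        })
        return InhibitionResult(ki, ki_se, kon, kon_se, koff, koff_se,
                                kinetics_class, cond, diagnostics)

    # fast-binding branch
    v0 = steady_state_velocity(uninhibited[0])
    table = pd.DataFrame({
        "inhibitor_conc": [c.inhibitor_conc for c in curves],
        "velocity": [steady_state_velocity(c) for c in curves],
    })
    morr = fit_morrison(table, enzyme_conc=cond.enzyme_conc, v0=None)
    if not morr.converged:
        raise AnalysisError("stage=morrison: tight-binding fit failed")
    factor = cond.factor
    ki = cheng_prusoff(morr["ki_app"], cond.substrate_conc, cond.km)
    ki_se = (morr.se("ki_app") / factor) if morr.se("ki_app") is not None else None
    nd = NotDetermined("not determined for linear progress curves")
    diagnostics.update({"velocity_table": table, "morrison": morr, "v0": v0})
    return InhibitionResult(ki, ki_se, nd, None, nd, None,
                            kinetics_class, cond, diagnostics)


def result_to_report_row(compound_id: str, res: InhibitionResult) -> dict:
    """Bench-unit report row (Ki nM, kon 10^3 M^-1 s^-1, koff 10^-3 s^-1)."""
    def fmt(value, scale):
        return value * scale if isinstance(value, float) else str(value)

    return {
        "compound_id": compound_id,
        "class": res.kinetics_class.label,
        "Ki_nM": res.ki * 1e9,
        "Ki_se": res.ki_se * 1e9 if res.ki_se is not None else "",
        "kon_1e3_Msi": fmt(res.kon, 1e-3),
        "kon_se": res.kon_se * 1e-3 if res.kon_se is not None else "",
        "koff_1e-3_si": fmt(res.koff, 1e3),
        "koff_se": res.koff_se * 1e3 if res.koff_se is not None else "",
    }
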