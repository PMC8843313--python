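"""Regression procedures recovering kinetic constants from assay data.

Per-curve nonlinear fits (progress equation, Michaelis-Menten, Morrison,
dose-response) use lmfit with positivity bounds; secondary analyses
(k_obs vs [I], titration endpoint) are ordinary linear least squares.
Standard errors come from the Gauss-Newton covariance approximation.
Classification of slow- vs fast-binding kinetics compares the straight-line
and progress-equation fits per curve with the small-sample-corrected Akaike
information criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd
import lmfit

from .kinetics import ProgressParams, progress_signal, michaelis_menten_rate, \
    steady_state_fraction, morrison_fraction

__all__ = [
    "FitResult",
    "KineticsClass",
    "fit_michaelis_menten",
    "fit_progress_curve",
    "fit_kobs_linear",
    "fit_dose_response",
    "fit_morrison",
    "fit_titration",
    "classify_progress_kinetics",
    "aicc",
    "steady_state_velocity",
]

#: AICc margin by which the exponential model must beat the straight line for
#: a curve to count as slow-binding evidence
CLASSIFIER_DELTA = 10.0

#: assumed relative resolution of the fluorescence readout: residual sums of
#: squares are floored at n*(RESOLUTION*signal range)^2 in model comparisons,
#: so that deviations far below what a plate reader can resolve (for
#: noiseless synthetic data, solver-precision residuals) carry no evidence
SIGNAL_RESOLUTION = 1e-3


def _rss_floor(y: np.ndarray) -> float:
    rng = float(np.max(y) - np.min(y))
    return len(y) * (SIGNAL_RESOLUTION * max(rng, np.finfo(float).tiny)) ** 2


@dataclass(frozen=True)
class FitResult:
    """Outcome of one regression.

    standard_errors is None when the fit did not converge or SEs are
    undefined (e.g. zero residual degrees of freedom); diagnostic messages
    accumulate in ``warnings``.
    """

    estimates: dict
    standard_errors: dict | None
    residual_sum_squares: float
    n_points: int
    converged: bool
    warnings: tuple = ()

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]

    def se(self, name: str) -> float | None:
        if self.standard_errors is None:
            return None
        return self.standard_errors.get(name)


@dataclass(frozen=True)
class KineticsClass:
    """Slow- vs fast-binding verdict from progress-curve shape.

    label is 'slow_binding', 'fast_binding', or None when the evidence is
    mixed; evidence is the median per-curve AICc difference (line minus
    exponential model; large positive favours slow binding).
    """

    label: str | None
    evidence: float
    votes: tuple = ()
    diagnostic: str = ""


def aicc(rss: float, n: int, k: int, floor: float = 0.0) -> float:
    """Small-sample-corrected Akaike information criterion for LS fits."""
    if n - k - 1 <= 0:
        return math.inf
    rss = max(rss, floor, np.finfo(float).tiny)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _lmfit_result(out: lmfit.minimizer.MinimizerResult | lmfit.model.ModelResult,
                  names, extra_warnings=()) -> FitResult:
    est = {p: float(out.params[p].value) for p in names}
    ses = None
    warns = list(extra_warnings)
    if out.success and out.errorbars:
        ses = {p: float(out.params[p].stderr) for p in names
               if out.params[p].stderr is not None}
    elif out.success:
        warns.append("standard errors unavailable")
    rss = float(np.sum(np.asarray(out.residual) ** 2))
    return FitResult(est, ses if out.success else None, rss, out.ndata,
                     bool(out.success), tuple(warns))


def fit_michaelis_menten(rate_table: pd.DataFrame) -> FitResult:
    """Fit v = Vmax*S/(Km+S); expects columns substrate_conc, rate.

    Requires >= 4 distinct substrate concentrations.  A Km estimate far above
    the sampled range (data effectively linear in S) is flagged as a boundary
    condition rather than raised.
    """
    s = rate_table["substrate_conc"].to_numpy(dtype=float)
    v = rate_table["rate"].to_numpy(dtype=float)
    if len(np.unique(s)) < 4:
        raise ValueError("need >= 4 distinct substrate concentrations")
    model = lmfit.Model(michaelis_menten_rate, independent_vars=["substrate_conc"])
    params = model.make_params(
        vmax=dict(value=float(np.max(v)) * 1.5 or 1.0, min=0),
        km=dict(value=float(np.median(s)), min=1e-12),
    )
    out = model.fit(v, params, substrate_conc=s)
    warns = []
    if out.success and out.params["km"].value > 100 * np.max(s):
        warns.append("km far above sampled range: data close to linear in S")
    return _lmfit_result(out, ("km", "vmax"), warns)


def _progress_init(t: np.ndarray, y: np.ndarray) -> ProgressParams:
    """Derivative-free starting values: vi from the first 10% of points,
    vs and the asymptote from the last 20%, d from the first point, kobs from
    a log-linear fit of the transient deficit below the asymptote."""
    n = len(t)
    ne, nl = max(3, n // 10), max(3, n // 5)
    vi = max(np.polyfit(t[:ne], y[:ne], 1)[0], 0.0)
    vs_c = np.polyfit(t[-nl:], y[-nl:], 1)
    vs = max(vs_c[0], 0.0)
    d = float(y[0])
    # deficit A*exp(-k t) between the late-time asymptote and the curve
    deficit = (vs_c[0] * t + vs_c[1]) - y
    pos = deficit > max(1e-12, 1e-3 * np.max(np.abs(deficit), initial=0.0))
    if pos.sum() >= 3:
        slope = np.polyfit(t[pos], np.log(deficit[pos]), 1)[0]
        kobs = max(-slope, 1e-2 / (t[-1] - t[0]))
    else:
        kobs = 3.0 / (t[-1] - t[0])
    return ProgressParams(vs=vs, vi=max(vi, 1e-30), kobs=kobs, d=d)


def _progress_model(t, vs, vi, kobs, d):
    return progress_signal(t, ProgressParams(vs=vs, vi=vi, kobs=kobs, d=d))


def fit_progress_curve(curve) -> FitResult:
    """Fit the slow-binding progress equation to one curve.

    Accepts a ProgressCurve (or any object with .times/.signal).  Flags
    kobs as unidentifiable when the curve is not meaningfully better
    described by the exponential model than by a straight line.
    """
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.signal, dtype=float)
    if len(t) < 20:
        raise ValueError("need >= 20 time points for a progress-curve fit")
    init = _progress_init(t, y)
    model = lmfit.Model(_progress_model, independent_vars=["t"])
    params = model.make_params(
        vs=dict(value=init.vs, min=0),
        vi=dict(value=init.vi, min=0),
        kobs=dict(value=init.kobs, min=1e-12),
        d=dict(value=init.d),
    )
    out = model.fit(y, params, t=t)
    warns = []
    if out.success:
        kobs = out.params["kobs"].value
        span = t[-1] - t[0]
        if span < 3.0 / kobs:
            warns.append("curve duration < 3/kobs: transient incompletely observed")
        # straight-line comparison for identifiability
        line_rss = float(np.sum((y - np.polyval(np.polyfit(t, y, 1), t)) ** 2))
        exp_rss = float(np.sum(out.residual ** 2))
        floor = _rss_floor(y)
        delta = aicc(line_rss, len(t), 2, floor) - aicc(exp_rss, len(t), 4, floor)
        if delta < 2.0:
            warns.append("kobs unidentifiable: no support over straight line")
    return _lmfit_result(out, ("vs", "vi", "kobs", "d"), warns)


def _ols(x: np.ndarray, y: np.ndarray, names=("slope", "intercept")):
    """Straight-line LS with Gauss-Newton SEs; SEs undefined at n == 2."""
    a = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ coef
    rss = float(resid @ resid)
    dof = len(x) - 2
    ses = None
    if dof > 0:
        cov = rss / dof * np.linalg.inv(a.T @ a)
        ses = dict(zip(names, np.sqrt(np.diag(cov))))
    return dict(zip(names, map(float, coef))), ses, rss


def fit_kobs_linear(kobs_table: pd.DataFrame) -> FitResult:
    """OLS of k_obs against [I]: slope k'on, intercept koff.

    Expects columns inhibitor_conc (M) and kobs (1/s), >= 3 concentrations
    for standard errors (2 give an exact interpolation, flagged).
    """
    df = kobs_table.sort_values("inhibitor_conc")
    x = df["inhibitor_conc"].to_numpy(dtype=float)
    y = df["kobs"].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 inhibitor concentrations")
    est, ses, rss = _ols(x, y, names=("kon_app", "koff"))
    warns = []
    if ses is None:
        warns.append("standard errors undefined with 2 points")
    if est["koff"] < 0:
        warns.append("negative fitted intercept: koff is physically >= 0")
    return FitResult(est, ses, rss, len(x), True, tuple(warns))


def fit_dose_response(vs_table: pd.DataFrame) -> FitResult:
    """Classical competitive dose-response fit vs/v0 = 1/(1+[I]/Ki').

    Expects columns inhibitor_conc (M) and fraction in (0, 1]; flags an
    unidentifiable Ki' when no inhibition is seen (all fractions ~ 1).
    """
    df = vs_table.sort_values("inhibitor_conc")
    x = df["inhibitor_conc"].to_numpy(dtype=float)
    f = df["fraction"].to_numpy(dtype=float)
    if np.any(f <= 0) or np.any(f > 1.0 + 1e-9):
        raise ValueError("fractions must lie in (0, 1]")
    warns = []
    if np.all(f > 0.9):
        warns.append("ki_app unidentifiable: no appreciable inhibition observed")
    model = lmfit.Model(steady_state_fraction, independent_vars=["inhibitor_conc"])
    half = np.interp(0.5, f[::-1], x[::-1]) if f.min() < 0.5 < f.max() else np.median(x[x > 0])
    params = model.make_params(ki_app=dict(value=float(max(half, 1e-15)), min=1e-18))
    out = model.fit(f, params, inhibitor_conc=x)
    return _lmfit_result(out, ("ki_app",), warns)


def fit_morrison(velocity_table: pd.DataFrame, enzyme_conc: float,
                 v0: float | None = None) -> FitResult:
    """Morrison tight-binding fit of steady-state velocities.

    Expects columns inhibitor_conc (M) and velocity; E0 is fixed (known from
    titration).  v0 is fitted unless supplied; an [I]=0 row initialises it.
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be strictly positive")
    df = velocity_table.sort_values("inhibitor_conc")
    x = df["inhibitor_conc"].to_numpy(dtype=float)
    v = df["velocity"].to_numpy(dtype=float)
    warns = []
    if np.all(x == 0):
        return FitResult({"ki_app": math.nan}, None, 0.0, len(x), False,
                         ("ki_app unidentifiable: no inhibited velocities",))

    def model_fn(inhibitor_conc, ki_app, v0_):
        return v0_ * morrison_fraction(enzyme_conc, inhibitor_conc, ki_app)

    model = lmfit.Model(model_fn, independent_vars=["inhibitor_conc"])
    v0_init = v0 if v0 is not None else (v[x == 0].mean() if np.any(x == 0) else v.max())
    params = model.make_params(
        ki_app=dict(value=enzyme_conc * 0.1, min=1e-18),
        v0_=dict(value=float(v0_init), min=0, vary=v0 is None),
    )
    out = model.fit(v, params, inhibitor_conc=x)
    res = _lmfit_result(out, ("ki_app", "v0_"), warns)
    est = dict(res.estimates)
    est["v0"] = est.pop("v0_")
    ses = res.standard_errors
    if ses is not None and "v0_" in ses:
        ses = dict(ses)
        ses["v0"] = ses.pop("v0_")
    return FitResult(est, ses, res.residual_sum_squares, res.n_points,
                     res.converged, res.warnings)


def fit_titration(activity_table: pd.DataFrame) -> FitResult:
    """Active-site titration endpoint: x-intercept of the linear segment.

    Expects columns titrant_conc, activity.  Points below 10% of the maximal
    activity are excluded from the line (curvature near the endpoint); a
    non-decreasing profile is a failure, not an exception.
    """
    df = activity_table.sort_values("titrant_conc")
    c = df["titrant_conc"].to_numpy(dtype=float)
    a = df["activity"].to_numpy(dtype=float)
    a_max = float(np.max(a))
    keep = a >= 0.1 * a_max
    if keep.sum() < 2:
        return FitResult({"enzyme_conc": math.nan}, None, 0.0, len(c), False,
                         ("fewer than 2 points in the linear segment",))
    est, ses, rss = _ols(c[keep], a[keep])
    if est["slope"] >= 0:
        return FitResult({"enzyme_conc": math.nan}, None, rss, int(keep.sum()),
                         False, ("no decreasing linear segment",))
    e0 = -est["intercept"] / est["slope"]
    ses_out = None
    if ses is not None and est["intercept"] != 0:
        rel = math.sqrt((ses["slope"] / est["slope"]) ** 2
                        + (ses["intercept"] / est["intercept"]) ** 2)
        ses_out = {"enzyme_conc": abs(e0) * rel}
    return FitResult({"enzyme_conc": float(e0), **est}, ses_out, rss,
                     int(keep.sum()), True, ())


def steady_state_velocity(curve, burn_in: float = 300.0) -> float:
    """Steady-state slope of a (near-)linear progress curve.

    Fits a straight line after discarding an initial burn-in window during
    which fast binding equilibrates.
    """
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.signal, dtype=float)
    m = t >= burn_in
    if m.sum() < 3:
        m = slice(None)
    return float(np.polyfit(t[m], y[m], 1)[0])


def classify_progress_kinetics(curves) -> KineticsClass:
    """Slow- vs fast-binding classification from inhibited progress curves.

    Per curve, the straight line and the progress equation are compared by
    AICc.  A curve votes slow-binding when the exponential model is preferred
    by more than ``CLASSIFIER_DELTA`` *and* its fitted transient actually
    develops within the assay window (kobs * duration >= 1) — without the
    second condition any slow systematic drift (e.g. mild substrate
    depletion) would masquerade as slow-binding kinetics.  The label follows
    the majority of inhibited curves and is withheld on a tie.
    """
    inhibited = [c for c in curves if getattr(c, "inhibitor_conc", 1.0) > 0]
    if len(inhibited) < 2:
        raise ValueError("need >= 2 inhibited curves to classify")
    votes = []
    deltas = []
    for c in inhibited:
        t = np.asarray(c.times, dtype=float)
        y = np.asarray(c.signal, dtype=float)
        n = len(t)
        line_rss = float(np.sum((y - np.polyval(np.polyfit(t, y, 1), t)) ** 2))
        fit = fit_progress_curve(c)
        if not fit.converged:
            votes.append(None)
            deltas.append(math.nan)
            continue
        floor = _rss_floor(y)
        delta = aicc(line_rss, n, 2, floor) - aicc(fit.residual_sum_squares, n, 4, floor)
        deltas.append(delta)
        transient_seen = fit["kobs"] * (t[-1] - t[0]) >= 1.0
        votes.append("slow_binding" if (delta > CLASSIFIER_DELTA and transient_seen)
                     else "fast_binding")
    valid = [v for v in votes if v is not None]
    evidence = float(np.nanmedian(deltas)) if deltas else math.nan
    if not valid:
        return KineticsClass(None, evidence, tuple(votes), "no curve fit converged")
    n_slow = valid.count("slow_binding")
    if n_slow * 2 == len(valid):
        return KineticsClass(None, evidence, tuple(votes),
                             "evidence split evenly between classes")
    label = "slow_binding" if n_slow * 2 > len(valid) else "fast_binding"
    return KineticsClass(label, evidence, tuple(votes))
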