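"""Solid-state kinetics of thermal denaturation under a linear heating ramp.

A denaturation stage is modelled as a single-step reaction with conversion
degree alpha in [0, 1] obeying

    d(alpha)/dt = A * exp(-E / (R*T)) * f(alpha),      T = T0 + beta*t,

with pre-exponential factor A (1/min), activation energy E (J/mol) and a
reaction model f(alpha).  Two models are registered: first-order F1
(f = 1 - alpha, integral form g = -ln(1 - alpha)) and second-order F2
(f = (1 - alpha)^2, g = (1 - alpha)^-1 - 1).

Parameters are estimated by the Coats-Redfern linearization

    ln(g(alpha) / T^2) = ln(A*R / (beta*E)) - E / (R*T),

an ordinary least-squares line in 1/T whose slope yields E and whose
intercept yields A.  The classical (1 - 2RT/E) correction factor is
dropped; for protein denaturation E/(R*T) is of order 30-150 and the
induced bias in E is below 0.1%.  Model selection maximizes the r^2 of
the linearized fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import Thermogram, CELSIUS_TO_KELVIN
from .peaks import Peak

__all__ = [
    "R_GAS",
    "KineticModelDef",
    "MODELS",
    "model_g",
    "model_f",
    "ConversionCurve",
    "KineticFit",
    "conversion_from_peak",
    "coats_redfern_fit",
    "select_model",
    "reconstruct_alpha",
    "aggregate_fits",
]

#: Universal gas constant, J/(mol*K).
R_GAS = 8.314


@dataclass(frozen=True)
class KineticModelDef:
    """A reaction model: integral form g(alpha) and differential form
    f(alpha) = 1 / g'(alpha).  ``order`` ranks models for tie-breaking."""

    symbol: str
    g: Callable[[np.ndarray], np.ndarray]
    f: Callable[[np.ndarray], np.ndarray]
    order: int


MODELS: dict[str, KineticModelDef] = {
    "F1": KineticModelDef("F1", g=lambda a: -np.log1p(-a), f=lambda a: 1.0 - a, order=1),
    "F2": KineticModelDef("F2", g=lambda a: 1.0 / (1.0 - a) - 1.0, f=lambda a: (1.0 - a) ** 2, order=2),
}


def _get_model(symbol: str) -> KineticModelDef:
    try:
        return MODELS[symbol]
    except KeyError:
        raise ValueError(f"unknown kinetic model {symbol!r}; registered: {sorted(MODELS)}")


def _check_alpha(alpha) -> np.ndarray:
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0) or np.any(a >= 1):
        raise ValueError("alpha must lie in [0, 1)")
    return a


def model_g(symbol: str, alpha):
    """Integral kinetic model g(alpha) for a registered model symbol."""
    out = _get_model(symbol).g(_check_alpha(alpha))
    return float(out) if np.isscalar(alpha) else out


def model_f(symbol: str, alpha):
    """Differential kinetic model f(alpha) = 1/g'(alpha)."""
    out = _get_model(symbol).f(_check_alpha(alpha))
    return float(out) if np.isscalar(alpha) else out


@dataclass(frozen=True)
class ConversionCurve:
    """Degree of transformation alpha(T) for one denaturation stage.

    Temperature is in kelvin and strictly increasing; alpha is
    nondecreasing within floating-point tolerance and bounded in [0, 1].
    """

    temperature: np.ndarray
    alpha: np.ndarray
    stage: int = 1

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        a = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "alpha", a)
        if t.size != a.size:
            raise ValueError("temperature and alpha must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature must be strictly increasing (K)")
        if np.any(a < -1e-12) or np.any(a > 1.0 + 1e-12):
            raise ValueError("alpha must lie in [0, 1]")
        if np.any(np.diff(a) < -1e-9):
            raise ValueError("alpha must be nondecreasing")

    @property
    def temperature_C(self) -> np.ndarray:
        return self.temperature - CELSIUS_TO_KELVIN


@dataclass(frozen=True)
class KineticFit:
    """Arrhenius parameters for one stage from a Coats-Redfern regression."""

    model: str
    E: float                      # activation energy, J/mol
    A: float                      # pre-exponential factor, 1/min
    r_squared: float
    alpha_window: tuple[float, float]
    n_points: int
    slope: float = np.nan         # slope of ln(g/T^2) vs 1/T, K
    intercept: float = np.nan
    accepted: bool = True         # False when the regression gives E <= 0
    Td_C: float = np.nan          # peak temperature, carried for reporting


def _flank_tail_area(t: np.ndarray, hf: np.ndarray, side: str,
                     n_fit: int = 10) -> float:
    """Area of the peak tail cut off beyond a window boundary.

    The flank of an Arrhenius-driven transition decays close to
    exponentially in temperature, so the missing tail is estimated as
    y_b / |m| with y_b the boundary signal and m the local slope of
    ln(heat flow) fitted over the ``n_fit`` innermost points.  Returns 0
    when the flank does not decay outward (no tail to extrapolate).
    """
    if side == "left":
        seg_t, seg_y = t[:n_fit], hf[:n_fit]
        y_b = hf[0]
    else:
        seg_t, seg_y = t[-n_fit:], hf[-n_fit:]
        y_b = hf[-1]
    pos = seg_y > 0
    if y_b <= 0 or pos.sum() < 3:
        return 0.0
    m, _, _ = _ols_line(seg_t[pos], np.log(seg_y[pos]))
    # left flank must rise inward (m > 0), right flank must fall (m < 0)
    if (side == "left" and m <= 0) or (side == "right" and m >= 0):
        return 0.0
    return float(y_b / abs(m))


def conversion_from_peak(tg: Thermogram, peak: Peak,
                         tail_correction: bool = True) -> ConversionCurve:
    """Conversion degree alpha(T) of one transition from a baseline-corrected
    thermogram: cumulative heat-flow area up to T over the total peak area.

    Negative corrected heat flow inside the window is clipped to zero so
    that alpha is nondecreasing; temperatures are returned in kelvin.
    Where a window boundary cuts a genuine low tail of the transition
    (boundary signal below 5% of the window maximum), the cut area is
    estimated by exponential-flank extrapolation and folded into the
    normalization, so alpha starts near (but not hard-pinned to) 0 and
    ends near 1 — without the correction, endpoint renormalization
    systematically steepens the Coats-Redfern line.  Boundaries that sit
    in the valley between overlapping peaks are left uncorrected.
    """
    from scipy.integrate import cumulative_trapezoid

    t = tg.temperature
    i0 = int(np.searchsorted(t, peak.T_onset, side="left"))
    i1 = int(np.searchsorted(t, peak.T_end, side="right"))
    if i1 - i0 < 3:
        raise ValueError("peak window contains fewer than 3 grid points")
    tt = t[i0:i1]
    hf = np.clip(tg.heat_flow[i0:i1], 0.0, None)
    cum = cumulative_trapezoid(hf, tt, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise ValueError("peak window has zero area; cannot define a conversion degree")

    a_lo = a_hi = 0.0
    if tail_correction:
        apex = float(np.max(hf))
        cap = 0.05 * total
        if hf[0] <= 0.05 * apex:
            a_lo = min(_flank_tail_area(tt, hf, "left"), cap)
        if hf[-1] <= 0.05 * apex:
            a_hi = min(_flank_tail_area(tt, hf, "right"), cap)
    alpha = (a_lo + cum) / (a_lo + total + a_hi)
    return ConversionCurve(tt + CELSIUS_TO_KELVIN, alpha, stage=peak.index)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and r^2 (squared Pearson correlation)."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    syy = np.sum((y - ym) ** 2)
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def coats_redfern_fit(curve: ConversionCurve, model: str, beta: float,
                      alpha_window: tuple[float, float] = (0.05, 0.95)) -> KineticFit:
    """Fit ln(g(alpha)/T^2) = ln(A*R/(beta*E)) - E/(R*T) by OLS.

    Only points with alpha inside ``alpha_window`` enter the regression
    (at least 10 required).  E = -slope*R; A = beta*E/R * exp(intercept).
    A regression with nonpositive slope-derived E is returned with
    ``accepted=False`` rather than raised.
    """
    mdl = _get_model(model)
    lo, hi = alpha_window
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("alpha_window must satisfy 0 < lo < hi < 1")
    mask = (curve.alpha >= lo) & (curve.alpha <= hi)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"only {n} points with alpha in [{lo}, {hi}]; need >= 10")
    T = curve.temperature[mask]
    a = curve.alpha[mask]
    y = np.log(mdl.g(a) / T**2)
    x = 1.0 / T
    slope, intercept, r2 = _ols_line(x, y)
    E = -slope * R_GAS
    if E > 0:
        A = beta * E / R_GAS * np.exp(intercept)
        accepted = True
    else:
        A = np.nan
        accepted = False
    return KineticFit(model=model, E=E, A=float(A), r_squared=r2,
                      alpha_window=(lo, hi), n_points=n,
                      slope=slope, intercept=intercept, accepted=accepted)


def select_model(curve: ConversionCurve, beta: float,
                 candidates: Sequence[str] = ("F1", "F2"),
                 alpha_window: tuple[float, float] = (0.05, 0.95)) -> KineticFit:
    """Fit every candidate model and return the one with maximal r^2.

    Candidates whose regression yields E <= 0 (or too few usable points)
    are rejected; a tie in r^2 within 1e-6 is broken in favour of the
    lower reaction order.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    fits: list[KineticFit] = []
    reasons: list[str] = []
    for sym in candidates:
        try:
            fit = coats_redfern_fit(curve, sym, beta, alpha_window)
        except ValueError as exc:
            reasons.append(f"{sym}: {exc}")
            continue
        if not fit.accepted:
            reasons.append(f"{sym}: nonpositive activation energy")
            continue
        fits.append(fit)
    if not fits:
        raise ValueError("no candidate model admissible: " + "; ".join(reasons))
    best_r2 = max(f.r_squared for f in fits)
    tied = [f for f in fits if best_r2 - f.r_squared < 1e-6]
    tied.sort(key=lambda f: _get_model(f.model).order)
    return tied[0]


def reconstruct_alpha(fit: KineticFit, T_grid: np.ndarray, beta: float,
                      alpha0: float = 0.0) -> ConversionCurve:
    """Forward-integrate the fitted (model, E, A) to a theoretical alpha(T)."""
    from .simulate import KineticPeakSpec, simulate_conversion

    if not fit.accepted:
        raise ValueError("cannot reconstruct from a rejected fit (E <= 0)")
    spec = KineticPeakSpec(model=fit.model, E=fit.E, A=fit.A, delta_H=1.0)
    curve = simulate_conversion(spec, beta, np.asarray(T_grid, dtype=float), alpha0=alpha0)
    return ConversionCurve(curve.temperature, curve.alpha, stage=0)


def _mode(values: pd.Series):
    m = values.mode()
    return m.iloc[0] if len(m) else np.nan


def aggregate_fits(table: pd.DataFrame, geometric_A: bool = False) -> pd.DataFrame:
    """Per-peak averages across samples of a per-sample results table.

    ``table`` follows the results schema with columns ``peak``, ``Td_C``,
    ``model``, ``E_J_per_mol``, ``A_per_min``.  Means are arithmetic;
    standard deviations use the n-1 denominator and are reported as 0 for
    a single value.  A is averaged in linear space by default
    (``geometric_A=True`` switches to the geometric mean with the SD of
    log10 A).  The modal model symbol is reported per peak.
    """
    required = {"peak", "Td_C", "model", "E_J_per_mol", "A_per_min"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"results table is missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("results table is empty")

    def _sd(v):
        return 0.0 if len(v) < 2 else float(np.std(v, ddof=1))

    rows = []
    for peak, grp in table.groupby("peak", sort=True):
        A = grp["A_per_min"].to_numpy(dtype=float)
        if geometric_A:
            logA = np.log10(A)
            a_mean, a_sd = float(10 ** logA.mean()), _sd(logA)
        else:
            a_mean, a_sd = float(A.mean()), _sd(A)
        rows.append({
            "peak": peak,
            "Td_mean": round(float(grp["Td_C"].mean()), 2),
            "Td_sd": round(_sd(grp["Td_C"].to_numpy(dtype=float)), 2),
            "model": _mode(grp["model"]),
            "E_mean": round(float(grp["E_J_per_mol"].mean()), 2),
            "E_sd": round(_sd(grp["E_J_per_mol"].to_numpy(dtype=float)), 2),
            "A_mean": a_mean,
            "A_sd": a_sd,
            "n": len(grp),
        })
    return pd.DataFrame(rows)
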