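"""Baseline correction, transition segmentation and per-peak enthalpy for
DSC thermograms.

Overlapping endothermic transitions are separated on the smoothed,
baseline-corrected signal: apices are the prominent local maxima, the
boundary between adjacent transitions is the local minimum of the
smoothed curve between their apices, and the outermost boundaries sit at
the first/last crossing of 1% of the respective peak height.  The
denaturation temperature T_d of a transition is the apex of the smoothed
corrected signal within its window, interpolated to sub-grid resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import find_peaks, savgol_filter

from .io import Thermogram

__all__ = ["Peak", "correct_baseline", "detect_peaks", "peak_enthalpy", "smooth_signal"]


@dataclass(frozen=True)
class Peak:
    """One denaturation transition on a baseline-corrected thermogram."""

    index: int          # 1-based stage number, ordered by T_d
    T_onset: float      # °C
    T_end: float        # °C
    T_d: float          # °C, apex of the smoothed corrected heat flow
    delta_H: float = np.nan   # J/g, filled by peak_enthalpy
    baseline_anchors: tuple[tuple[float, float], tuple[float, float]] | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not (self.T_onset < self.T_d < self.T_end):
            raise ValueError(
                f"peak {self.index}: need T_onset < T_d < T_end, got "
                f"({self.T_onset}, {self.T_d}, {self.T_end})")


def smooth_signal(values: np.ndarray, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing; the window is shrunk (kept odd) for short
    signals and the signal is returned unchanged when shorter than the
    polynomial order + 2."""
    n = len(values)
    window = min(window, n if n % 2 == 1 else n - 1)
    if window <= polyorder:
        return np.asarray(values, dtype=float).copy()
    return savgol_filter(values, window_length=window, polyorder=polyorder)


def correct_baseline(tg: Thermogram, T_onset: float, T_end: float) -> Thermogram:
    """Subtract the straight line through the signal at two anchor
    temperatures (instrumental baseline drift), leaving the corrected heat
    flow exactly zero at both anchors."""
    t = tg.temperature
    if not (t[0] <= T_onset < T_end <= t[-1]):
        raise ValueError(
            f"baseline anchors ({T_onset}, {T_end}) must be ordered and inside "
            f"the temperature range [{t[0]}, {t[-1]}]")
    y0 = float(np.interp(T_onset, t, tg.heat_flow))
    y1 = float(np.interp(T_end, t, tg.heat_flow))
    slope = (y1 - y0) / (T_end - T_onset)
    baseline = y0 + slope * (t - T_onset)
    return tg.with_heat_flow(tg.heat_flow - baseline)


def _refine_apex(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid apex via a parabola through the three points around i."""
    if i <= 0 or i >= len(t) - 1:
        return float(t[i])
    x0, x1, x2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    if denom == 0:
        return float(x1)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:
        return float(x1)
    apex = -b / (2 * a)
    return float(np.clip(apex, x0, x2))


def _first_crossing(t, y, start: int, threshold: float, direction: int) -> float:
    """Walk from ``start`` in ``direction`` until y drops below threshold;
    linear interpolation of the crossing temperature."""
    i = start
    while 0 <= i + direction < len(y) and y[i + direction] > threshold:
        i += direction
    j = i + direction
    if j < 0 or j >= len(y):
        return float(t[i])
    if y[i] == y[j]:
        return float(t[j])
    frac = (y[i] - threshold) / (y[i] - y[j])
    return float(t[i] + frac * (t[j] - t[i]))


def detect_peaks(tg: Thermogram, min_prominence: float = 0.05,
                 expected_n: int | None = None,
                 window: int = 11, polyorder: int = 3) -> list[Peak]:
    """Locate denaturation transitions on a baseline-corrected thermogram.

    Apices are local maxima of the Savitzky-Golay-smoothed signal with
    prominence at least ``min_prominence`` times the signal maximum.
    Adjacent peaks are split at the minimum of the smoothed signal between
    apices; the outermost onset/end lie at the 1%-of-peak-height
    crossings.  Returns an empty list if nothing is found.  When
    ``expected_n`` is given and not matched, the peaks carry a
    ``peak_count_mismatch`` flag instead of raising.
    """
    t = tg.temperature
    y = smooth_signal(tg.heat_flow, window, polyorder)
    ymax = float(np.max(y))
    if ymax <= 0:
        return []
    apices, _ = find_peaks(y, prominence=min_prominence * ymax)
    if len(apices) == 0:
        return []

    flags: tuple[str, ...] = ()
    if expected_n is not None and len(apices) != expected_n:
        flags = (f"peak_count_mismatch: found {len(apices)}, expected {expected_n}",)

    # boundaries: valley minima between apices, 1%-height crossings outside
    bounds = []
    left = _first_crossing(t, y, int(apices[0]), 0.01 * y[apices[0]], -1)
    bounds.append(left)
    for a, b in zip(apices[:-1], apices[1:]):
        valley = a + int(np.argmin(y[a:b + 1]))
        bounds.append(float(t[valley]))
    right = _first_crossing(t, y, int(apices[-1]), 0.01 * y[apices[-1]], +1)
    bounds.append(right)

    peaks = []
    for k, apex in enumerate(apices):
        td = _refine_apex(t, y, int(apex))
        lo, hi = bounds[k], bounds[k + 1]
        # guard against a refined apex landing on a boundary
        if not (lo < td < hi):
            td = float(np.clip(td, np.nextafter(lo, hi), np.nextafter(hi, lo)))
        peaks.append(Peak(index=k + 1, T_onset=lo, T_end=hi, T_d=round(td, 2),
                          flags=flags))
    return peaks


def peak_enthalpy(tg: Thermogram, peak: Peak) -> float:
    """Transition enthalpy in J/g: area of the baseline-corrected heat flow
    over time inside the peak window, divided by the sample mass.

    Heat flow is in mW and time in minutes (t = (T - T_onset)/beta), so
    the area in mW*min is multiplied by 60 to give mJ; negative corrected
    heat flow is clipped to zero.
    """
    if not tg.mass > 0:
        raise ValueError("mass must be positive")
    t = tg.temperature
    i0 = int(np.searchsorted(t, peak.T_onset, side="left"))
    i1 = int(np.searchsorted(t, peak.T_end, side="right"))
    if i1 - i0 < 2:
        raise ValueError("peak window contains fewer than 2 grid points")
    hf = np.clip(tg.heat_flow[i0:i1], 0.0, None)        # mW
    time_min = t[i0:i1] / tg.beta                       # min (offset cancels)
    area_mJ = trapezoid(hf, time_min) * 60.0
    return float(area_mJ / tg.mass)
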