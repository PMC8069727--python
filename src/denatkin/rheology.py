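"""Gelation features from oscillatory temperature sweeps.

The storage modulus of heated muscle tissue traces three regimes:
softening (S1) down to a minimum at the first inflexion point IP1 (onset
of protein denaturation), network build-up (S2) up to a maximum at IP2
(completion of denaturation), and thermohydrolytic weakening (S3)
afterwards.  The gel point T_gel is the bend of G'(T) inside S2 — the
temperature of maximum positive curvature of smoothed log G'.  All
derivative work is done on log G' so that the features are invariant to
modulus rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import RheoSweep
from .peaks import smooth_signal

__all__ = ["RheoFeatures", "phase_angle", "complex_modulus",
           "find_inflexions", "find_tgel", "segment_series"]


@dataclass(frozen=True)
class RheoFeatures:
    """Landmarks and derived quantities of one sweep."""

    IP1: float                 # °C, G' minimum: denaturation onset
    IP2: float                 # °C, G' maximum: denaturation completion
    T_gel: float               # °C, bend of log G' inside S2
    delta: np.ndarray          # degrees, per grid point
    complex_modulus: np.ndarray   # Pa, per grid point
    segments: tuple[slice, slice, slice]   # S1, S2, S3 index ranges

    def __post_init__(self):
        if not (self.IP1 < self.T_gel < self.IP2):
            raise ValueError("need IP1 < T_gel < IP2")
        if np.any(self.delta <= 0) or np.any(self.delta >= 90):
            raise ValueError("phase angle must lie strictly inside (0, 90) degrees")


def phase_angle(Gp, Gpp):
    """Phase shift angle delta = arctan(G''/G') in degrees.

    Low delta means a predominantly elastic (well-networked) material.
    """
    Gp = np.asarray(Gp, dtype=float)
    Gpp = np.asarray(Gpp, dtype=float)
    if np.any(Gp <= 0):
        raise ValueError("G' must be strictly positive")
    if np.any(Gpp < 0):
        raise ValueError("G'' must be nonnegative")
    out = np.degrees(np.arctan2(Gpp, Gp))
    return float(out) if out.ndim == 0 else out


def complex_modulus(Gp, Gpp):
    """Magnitude of the complex modulus, G* = sqrt(G'^2 + G''^2) (Pa)."""
    Gp = np.asarray(Gp, dtype=float)
    Gpp = np.asarray(Gpp, dtype=float)
    if np.any(Gp < 0) or np.any(Gpp < 0):
        raise ValueError("moduli must be nonnegative")
    if np.any((Gp == 0) & (Gpp == 0)):
        raise ValueError("G' and G'' cannot both be zero")
    out = np.hypot(Gp, Gpp)
    return float(out) if out.ndim == 0 else out


def _refine_extremum(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid extremum location via a parabola through three points."""
    if i <= 0 or i >= len(t) - 1:
        return float(t[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(t[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(t[i] + np.clip(shift, -1.0, 1.0) * (t[i + 1] - t[i]))


def _uniform_log_gp(sweep: RheoSweep, window: int, polyorder: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed log G' on a uniform grid (resampled if necessary)."""
    t = sweep.temperature
    dt = np.diff(t)
    if np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        tu = t
        logg = np.log(sweep.storage_modulus)
    else:
        tu = np.linspace(t[0], t[-1], t.size)
        logg = np.interp(tu, t, np.log(sweep.storage_modulus))
    return tu, smooth_signal(logg, window, polyorder)


def find_inflexions(sweep: RheoSweep, window: int = 11, polyorder: int = 3
                    ) -> tuple[float, float]:
    """Locate IP1 and IP2 on a sweep.

    IP1 is the global minimum of smoothed log G' within the lower half of
    the temperature range; IP2 is the global maximum above IP1.  Both are
    refined to sub-grid resolution by a local quadratic fit.  A sweep
    whose smoothed G' is monotone (extrema on the boundary) is rejected.
    """
    t = sweep.temperature
    if t.size < 30:
        raise ValueError("need at least 30 grid points")
    if t[-1] - t[0] < 40.0:
        raise ValueError("sweep must span at least 40 °C")
    tu, y = _uniform_log_gp(sweep, window, polyorder)

    half = int(np.searchsorted(tu, 0.5 * (tu[0] + tu[-1])))
    i_min = int(np.argmin(y[: half + 1]))
    if i_min == 0 or i_min >= half:
        raise ValueError("no interior G' minimum in the lower half of the "
                         "range; the sweep looks monotone")
    ip1 = _refine_extremum(tu, y, i_min)

    upper = y[i_min:]
    i_max = i_min + int(np.argmax(upper))
    if i_max <= i_min or i_max == tu.size - 1:
        raise ValueError("no interior G' maximum above IP1; the sweep looks "
                         "monotone")
    ip2 = _refine_extremum(tu, y, i_max)
    return ip1, ip2


def find_tgel(sweep: RheoSweep, IP1: float, IP2: float,
              window: int = 11, polyorder: int = 3,
              curvature_tol: float = 1e-6) -> float:
    """Gel point: temperature of maximum positive curvature of smoothed
    log G' strictly inside (IP1 + 2, IP2 - 2) °C.

    Curvature below ``curvature_tol`` (1/K^2) counts as numerically zero:
    a log G' that is linear through S2 has no bend and is rejected.
    """
    if not IP1 < IP2:
        raise ValueError("need IP1 < IP2")
    tu, y = _uniform_log_gp(sweep, window, polyorder)
    d2 = np.gradient(np.gradient(y, tu), tu)
    d2s = smooth_signal(d2, window, polyorder)
    mask = (tu > IP1 + 2.0) & (tu < IP2 - 2.0)
    if not np.any(mask):
        raise ValueError("window (IP1+2, IP2-2) contains no grid points")
    idx = np.flatnonzero(mask)
    j = idx[int(np.argmax(d2s[idx]))]
    if d2s[j] <= curvature_tol:
        raise ValueError("no positive-curvature bend inside (IP1+2, IP2-2); "
                         "log G' has no gel point there")
    return _refine_extremum(tu, d2s, int(j))


def segment_series(sweep: RheoSweep, IP1: float, IP2: float,
                   window: int = 11, polyorder: int = 3) -> RheoFeatures:
    """Assemble the full feature record: pointwise delta and G*, the gel
    point, and the S1/S2/S3 partition of the grid (S1: T <= IP1,
    S2: IP1 < T <= IP2, S3: T > IP2)."""
    t_gel = find_tgel(sweep, IP1, IP2, window, polyorder)
    t = sweep.temperature
    i1 = int(np.searchsorted(t, IP1, side="right"))
    i2 = int(np.searchsorted(t, IP2, side="right"))
    return RheoFeatures(
        IP1=IP1, IP2=IP2, T_gel=t_gel,
        delta=phase_angle(sweep.storage_modulus, sweep.loss_modulus),
        complex_modulus=complex_modulus(sweep.storage_modulus,
                                        sweep.loss_modulus),
        segments=(slice(0, i1), slice(i1, i2), slice(i2, t.size)),
    )
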