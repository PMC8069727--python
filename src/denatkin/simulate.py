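"""Synthetic DSC thermograms and oscillatory rheology sweeps with known
ground truth.

The DSC generator inverts the measurement model: each denaturation stage
contributes heat flow proportional to its reaction rate,

    hf_i(T) = mass * dH_i * beta * (d alpha_i / dT) / 60   [mW],

with alpha_i obtained by integrating d(alpha)/dT = (A/beta) *
exp(-E/(R*T)) * f(alpha) by a classical fixed-step 4th-order Runge-Kutta
scheme at an internal step of at most 0.1 K.  Summed stage signals plus a
linear instrument baseline and Gaussian noise give the thermogram; the
returned ground truth records each stage's numerically located
rate-maximum temperature from the noiseless signal.

Pre-exponential factors are placed from target peak temperatures through
the Kissinger relation  E*beta/(R*Tp^2) = A*exp(-E/(R*Tp)), which is
exact for first-order kinetics under this rate law; for other models the
generator refines A numerically so the simulated rate maximum lands on
the requested temperature.

The rheology generator builds log G'(T) as a C1 piecewise-cubic (PCHIP)
curve through knots shaped by three landmark temperatures: a minimum at
IP1 (onset of denaturation), a slope increase at T_gel (gel point) and a
maximum at IP2 (completion of denaturation), with G''(T) anchored to a
decline from its starting level and delta(20 C) fixed by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .io import Thermogram, RheoSweep, CELSIUS_TO_KELVIN
from .kinetics import ConversionCurve, MODELS, R_GAS

__all__ = [
    "KineticPeakSpec",
    "DscSimSpec",
    "RheoSimSpec",
    "PeakTruth",
    "DscGroundTruth",
    "kissinger_preexponential",
    "preexponential_for_peak",
    "simulate_conversion",
    "synthesize_dsc",
    "synthesize_rheo",
    "default_dsc_spec",
]


@dataclass(frozen=True)
class KineticPeakSpec:
    """Ground-truth kinetics of one denaturation stage."""

    model: str            # registered model symbol (F1, F2)
    E: float              # activation energy, J/mol
    A: float              # pre-exponential factor, 1/min
    delta_H: float        # stage enthalpy, J/g
    label: str = ""

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown kinetic model {self.model!r}")
        if not (self.E > 0 and self.A > 0 and self.delta_H > 0):
            raise ValueError("E, A and delta_H must all be positive")


@dataclass(frozen=True)
class DscSimSpec:
    """Recipe for a synthetic DSC thermogram."""

    peaks: tuple[KineticPeakSpec, ...]
    beta: float = 5.0             # K/min
    T_start: float = 20.0         # °C
    T_end: float = 95.0           # °C
    step: float = 0.1             # K, output grid spacing
    mass: float = 15.0            # mg
    baseline: tuple[float, float] = (0.0, 0.0)   # (intercept mW, slope mW/K)
    noise_sd: float = 0.0         # mW
    seed: int = 0

    def __post_init__(self):
        if not self.peaks:
            raise ValueError("at least one peak spec is required")
        if not self.T_start < self.T_end:
            raise ValueError("T_start must be below T_end")
        if not (self.step > 0 and self.beta > 0 and self.mass > 0):
            raise ValueError("step, beta and mass must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class RheoSimSpec:
    """Recipe for a synthetic oscillatory temperature sweep.

    Landmarks: G' minimum at ``ip1``, slope increase of log G' at
    ``t_gel`` and G' maximum at ``ip2``.  ``delta_start`` fixes the phase
    angle at 20 C, which together with ``gpp_start`` determines G'(20 C).
    ``slope_pre``/``slope_post`` are the log G' slopes (1/K) below/above
    the gel point.
    """

    ip1: float = 40.0             # °C
    t_gel: float = 53.0           # °C
    ip2: float = 70.0             # °C
    delta_start: float = 12.3     # degrees at 20 °C
    gpp_start: float = 2600.0     # Pa, G'' at 20 °C
    gpp_ip1: float = 1800.0       # Pa, G'' at IP1
    g_min: float = 9713.0         # Pa, G' at its IP1 minimum
    slope_pre: float = 0.008      # d log G'/dT on (IP1, T_gel), 1/K
    slope_post: float = 0.024     # d log G'/dT on (T_gel, IP2), 1/K
    noise_rel: float = 0.0        # relative (log-normal) noise
    seed: int = 0

    def __post_init__(self):
        if not (20.0 <= self.ip1 < self.t_gel < self.ip2 <= 85.0):
            raise ValueError("need 20 <= IP1 < T_gel < IP2 <= 85 (°C)")
        if not (self.ip1 + 2 < self.t_gel < self.ip2 - 2):
            raise ValueError("T_gel must lie strictly inside (IP1+2, IP2-2)")
        for name in ("gpp_start", "gpp_ip1", "g_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive (Pa)")
        if not (0.0 < self.slope_pre < self.slope_post):
            raise ValueError("need 0 < slope_pre < slope_post")
        if not (0.0 < self.delta_start < 90.0):
            raise ValueError("delta_start must be in (0, 90) degrees")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be nonnegative")

    @property
    def g_start(self) -> float:
        """G'(20 C) implied by delta_start and gpp_start (Pa)."""
        return self.gpp_start / math.tan(math.radians(self.delta_start))


@dataclass(frozen=True)
class PeakTruth:
    """Ground truth for one simulated stage."""

    T_d: float            # °C, numerically located rate maximum (noiseless)
    E: float
    A: float
    model: str
    delta_H: float


@dataclass(frozen=True)
class DscGroundTruth:
    peaks: tuple[PeakTruth, ...]
    overlap_warning: bool
    noiseless: np.ndarray                 # peak signal sum, no baseline/noise (mW)
    components: tuple[np.ndarray, ...]    # per-peak noiseless signals (mW)


def kissinger_preexponential(E: float, T_peak_K: float, beta: float) -> float:
    """Pre-exponential factor A (1/min) placing a first-order rate maximum
    at T_peak_K (K) under heating rate beta (K/min):
    A = beta*E/(R*Tp^2) * exp(E/(R*Tp))."""
    if not (E > 0 and T_peak_K > 0 and beta > 0):
        raise ValueError("E, T_peak_K and beta must be positive")
    return beta * E / (R_GAS * T_peak_K**2) * math.exp(E / (R_GAS * T_peak_K))


def _rate_grid(spec: KineticPeakSpec, beta: float, T_K: np.ndarray,
               alpha: np.ndarray) -> np.ndarray:
    """d alpha/dT (1/K) along an already-integrated trajectory."""
    mdl = MODELS[spec.model]
    if spec.A == 0:
        return np.zeros_like(T_K)
    ln_k = math.log(spec.A / beta) - spec.E / (R_GAS * T_K)
    return np.exp(ln_k) * mdl.f(np.clip(alpha, 0.0, 1.0))


def _refine_max(x: np.ndarray, y: np.ndarray) -> float:
    i = int(np.argmax(y))
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(x[i])
    return float(x[i] + 0.5 * (y0 - y2) / denom * (x[i + 1] - x[i]))


def rate_maximum_temperature(spec: KineticPeakSpec, beta: float,
                             T_center_K: float, half_span: float = 60.0,
                             step: float = 0.05) -> float:
    """Numerically locate the temperature (K) of maximum d alpha/dT."""
    lo = max(T_center_K - half_span, 200.0)
    grid = np.arange(lo, T_center_K + half_span + step, step)
    curve = simulate_conversion(spec, beta, grid, alpha0=0.0, max_step=step)
    rate = _rate_grid(spec, beta, grid, curve.alpha)
    return _refine_max(grid, rate)


def preexponential_for_peak(model: str, E: float, T_peak_K: float,
                            beta: float) -> float:
    """A (1/min) placing the numerical rate maximum of ``model`` at
    T_peak_K.  Exact Kissinger closed form for F1; for other models the
    closed form seeds a bracketing search on log10 A."""
    a0 = kissinger_preexponential(E, T_peak_K, beta)
    if model == "F1":
        return a0

    def offset(log10_a: float) -> float:
        spec = KineticPeakSpec(model=model, E=E, A=10.0**log10_a, delta_H=1.0)
        return rate_maximum_temperature(spec, beta, T_peak_K) - T_peak_K

    x0 = math.log10(a0)
    return 10.0 ** brentq(offset, x0 - 1.0, x0 + 1.0, xtol=1e-10)


def simulate_conversion(spec: KineticPeakSpec, beta: float, T_grid: np.ndarray,
                        alpha0: float = 0.0, max_step: float = 0.1) -> ConversionCurve:
    """Integrate d alpha/dT = (A/beta)*exp(-E/(R*T))*f(alpha) over T_grid (K).

    Classical 4th-order Runge-Kutta with a fixed internal step of at most
    ``max_step`` K, refined independently of the output grid.  Alpha is
    clamped to [alpha0, 1) and is nondecreasing by construction.
    """
    T = np.asarray(T_grid, dtype=float)
    if T.ndim != 1 or T.size < 2:
        raise ValueError("T_grid must be a 1-d array with at least 2 points")
    if not np.all(np.diff(T) > 0):
        raise ValueError("T_grid must be strictly increasing (K)")
    if T[0] <= 0:
        raise ValueError("temperatures must be positive kelvin")
    if not (0.0 <= alpha0 < 1.0):
        raise ValueError("alpha0 must lie in [0, 1)")
    if spec.E < 0:
        raise ValueError("activation energy must be nonnegative")

    mdl = MODELS[spec.model]
    cap = 1.0 - 1e-12

    if spec.A == 0:
        return ConversionCurve(T, np.full_like(T, alpha0), stage=1)

    ln_a_beta = math.log(spec.A / beta)
    e_r = spec.E / R_GAS
    fmod = mdl.f

    def rate(t: float, a: float) -> float:
        if a >= 1.0:
            return 0.0
        return math.exp(ln_a_beta - e_r / t) * fmod(a)

    out = np.empty_like(T)
    a = float(alpha0)
    out[0] = a
    for i in range(T.size - 1):
        t0, t1 = T[i], T[i + 1]
        n_sub = max(1, math.ceil((t1 - t0) / max_step))
        h = (t1 - t0) / n_sub
        t = t0
        for _ in range(n_sub):
            k1 = rate(t, a)
            k2 = rate(t + 0.5 * h, a + 0.5 * h * k1)
            k3 = rate(t + 0.5 * h, a + 0.5 * h * k2)
            k4 = rate(t + h, a + h * k3)
            a_new = a + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            a = min(max(a_new, a), cap)
            t += h
        out[i + 1] = a
    return ConversionCurve(T, out, stage=1)


def synthesize_dsc(spec: DscSimSpec) -> tuple[Thermogram, DscGroundTruth]:
    """Build a thermogram from per-stage kinetics plus baseline and noise.

    Heat flow of stage i is mass*dH_i*beta*(d alpha_i/dT)/60 in mW (the
    factor 60 converts per-minute reaction rates to per-second heat).
    Ground truth reports each stage's rate-maximum temperature from the
    noiseless signal; maxima closer than 2 K raise the overlap flag.
    The Gaussian noise stream is fully determined by ``spec.seed``.
    """
    n = int(round((spec.T_end - spec.T_start) / spec.step)) + 1
    T_C = spec.T_start + spec.step * np.arange(n)
    T_K = T_C + CELSIUS_TO_KELVIN

    components = []
    truths = []
    for pk in spec.peaks:
        curve = simulate_conversion(pk, spec.beta, T_K, alpha0=0.0,
                                    max_step=min(0.1, spec.step))
        dadT = _rate_grid(pk, spec.beta, T_K, curve.alpha)
        hf = spec.mass * pk.delta_H * spec.beta * dadT / 60.0
        components.append(hf)
        truths.append(PeakTruth(
            T_d=round(_refine_max(T_C, dadT), 4), E=pk.E, A=pk.A,
            model=pk.model, delta_H=pk.delta_H))

    noiseless = np.sum(components, axis=0)
    td = np.array([p.T_d for p in truths])
    overlap = bool(np.any(np.diff(np.sort(td)) < 2.0))

    intercept, slope = spec.baseline
    baseline = intercept + slope * (T_C - spec.T_start)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0

    tg = Thermogram(T_C, noiseless + baseline + noise, mass=spec.mass,
                    beta=spec.beta, sample_id=f"sim-{spec.seed}")
    truth = DscGroundTruth(peaks=tuple(truths), overlap_warning=overlap,
                           noiseless=noiseless, components=tuple(components))
    return tg, truth


#: Default four-stage recipe: rate maxima at the average denaturation
#: temperatures of the four herring muscle protein fractions (myosin,
#: sarcoplasm, connective tissue, actin), models F1/F1/F2/F1.
DEFAULT_PEAK_TD_C = (43.45, 56.79, 69.01, 77.91)
DEFAULT_PEAK_MODELS = ("F1", "F1", "F2", "F1")
DEFAULT_PEAK_E = (3.0e5, 3.2e5, 5.0e5, 4.2e5)      # J/mol
DEFAULT_PEAK_DH = (1.2, 0.8, 0.5, 0.7)             # J/g
DEFAULT_PEAK_LABELS = ("myosin", "sarcoplasm", "connective tissue", "actin")


def default_dsc_spec(noise_sd: float = 0.0, seed: int = 0,
                     baseline: tuple[float, float] = (0.0, 0.0),
                     beta: float = 5.0, mass: float = 15.0,
                     step: float = 0.1) -> DscSimSpec:
    """Four overlapping endothermic stages between ~40 and ~82 °C at
    beta = 5 K/min, placed at the default denaturation temperatures."""
    peaks = tuple(
        KineticPeakSpec(
            model=m, E=e,
            A=preexponential_for_peak(m, e, td + CELSIUS_TO_KELVIN, beta),
            delta_H=dh, label=lab)
        for td, m, e, dh, lab in zip(DEFAULT_PEAK_TD_C, DEFAULT_PEAK_MODELS,
                                     DEFAULT_PEAK_E, DEFAULT_PEAK_DH,
                                     DEFAULT_PEAK_LABELS))
    return DscSimSpec(peaks=peaks, beta=beta, T_start=20.0, T_end=95.0,
                      step=step, mass=mass, baseline=baseline,
                      noise_sd=noise_sd, seed=seed)


def _gprime_knots(spec: RheoSimSpec, T_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Knots of log G'(T): gentle valley at IP1, slope break at T_gel,
    maximum at IP2, mild plateau then decline."""
    v_min = math.log(spec.g_min)
    v_start = math.log(spec.g_start)
    if v_start <= v_min:
        raise ValueError("g_start implied by delta_start must exceed g_min")
    v_gel = v_min + spec.slope_pre * (spec.t_gel - spec.ip1)
    v_ip2 = v_gel + spec.slope_post * (spec.ip2 - spec.t_gel)

    ts = [20.0]
    vs = [v_start]
    mid1 = 0.5 * (20.0 + spec.ip1)
    if mid1 > 20.5:
        ts.append(mid1)
        vs.append(v_min + 0.55 * (v_start - v_min))
    if spec.ip1 - 3.0 > mid1 + 0.5:
        ts.append(spec.ip1 - 3.0)
        vs.append(v_min + 0.004)
    ts.append(spec.ip1)
    vs.append(v_min)
    for t in (spec.t_gel - 2.0, spec.t_gel):
        if t > ts[-1] + 0.25:
            ts.append(t)
            vs.append(v_min + spec.slope_pre * (t - spec.ip1))
    for t in (spec.t_gel + 2.0, 0.5 * (spec.t_gel + spec.ip2)):
        if ts[-1] + 0.25 < t < spec.ip2 - 0.25:
            ts.append(t)
            vs.append(v_gel + spec.slope_post * (t - spec.t_gel))
    ts.append(spec.ip2)
    vs.append(v_ip2)
    plateau_end = min(spec.ip2 + 5.0, T_end - 1.0)
    if plateau_end > spec.ip2 + 0.5:
        ts.append(plateau_end)
        vs.append(v_ip2 - 0.01)
    ts.append(T_end)
    vs.append(v_ip2 - 0.15)
    return np.array(ts), np.array(vs)


def _gdouble_knots(spec: RheoSimSpec, T_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Knots of G''(T): decline to IP1, slow decline to mid-S2, slight
    recovery at IP2, decline afterwards."""
    mid = 0.5 * (spec.ip1 + spec.ip2)
    ts = [20.0, spec.ip1, mid, spec.ip2]
    vs = [spec.gpp_start, spec.gpp_ip1, 0.944 * spec.gpp_ip1, 0.972 * spec.gpp_ip1]
    tail = min(spec.ip2 + 5.0, T_end - 1.0)
    if tail > spec.ip2 + 0.5:
        ts.append(tail)
        vs.append(0.917 * spec.gpp_ip1)
    ts.append(T_end)
    vs.append(0.722 * spec.gpp_ip1)
    return np.array(ts), np.array(vs)


def synthesize_rheo(spec: RheoSimSpec, T_grid: np.ndarray | None = None,
                    frequency: float = 1.0) -> tuple[RheoSweep, tuple[float, float, float]]:
    """Synthetic temperature sweep of G' and G'' with known landmarks.

    Returns the sweep and the ground truth (IP1, T_gel, IP2) in °C.
    Noise is multiplicative log-normal, seeded by ``spec.seed``.
    """
    if T_grid is None:
        T_grid = np.arange(20.0, 85.0 + 1e-9, 0.25)
    T = np.asarray(T_grid, dtype=float)
    if not np.all(np.diff(T) > 0):
        raise ValueError("T_grid must be strictly increasing")
    if T[0] < 20.0 - 1e-9 or T[-1] > 85.0 + 1e-9:
        raise ValueError("T_grid must lie within [20, 85] °C")

    t_end = 85.0
    kt, kv = _gprime_knots(spec, t_end)
    gp = np.exp(PchipInterpolator(kt, kv)(T))
    kt2, kv2 = _gdouble_knots(spec, t_end)
    gpp = PchipInterpolator(kt2, kv2)(T)

    if spec.noise_rel > 0:
        rng = np.random.default_rng(spec.seed)
        gp = gp * np.exp(rng.normal(0.0, spec.noise_rel, size=T.size))
        gpp = gpp * np.exp(rng.normal(0.0, spec.noise_rel, size=T.size))

    sweep = RheoSweep(T, gp, gpp, frequency=frequency,
                      sample_id=f"rheo-sim-{spec.seed}")
    return sweep, (spec.ip1, spec.t_gel, spec.ip2)
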