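"""Containers and CSV I/O for thermograms, rheology sweeps and results tables.

All on-disk temperatures are degrees Celsius; kinetics modules convert to
kelvin internally (T_K = T_C + 273.15).  Files are plain comma-separated
text with a dot decimal separator; a single header line is auto-detected
(non-numeric first row) and otherwise optional.  Endothermic transitions
are stored as positive heat flow.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Thermogram",
    "RheoSweep",
    "RunConfig",
    "read_thermogram",
    "write_thermogram",
    "read_rheo_sweep",
    "write_rheo_sweep",
    "write_kinetics_table",
    "CELSIUS_TO_KELVIN",
]

CELSIUS_TO_KELVIN = 273.15


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class Thermogram:
    """A DSC record: heat flow (mW, endothermic positive) on a strictly
    increasing temperature grid (°C), with sample mass (mg) and the linear
    heating rate beta (K/min)."""

    temperature: np.ndarray
    heat_flow: np.ndarray
    mass: float
    beta: float
    sample_id: str = ""

    def __post_init__(self):
        t = _as_float_array(self.temperature, "temperature")
        hf = _as_float_array(self.heat_flow, "heat_flow")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "heat_flow", hf)
        if t.size != hf.size:
            raise ValueError("temperature and heat_flow must have equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("temperature must be strictly increasing")
        if not self.mass > 0:
            raise ValueError("mass must be positive (mg)")
        if not self.beta > 0:
            raise ValueError("beta must be positive (K/min)")

    @property
    def temperature_K(self) -> np.ndarray:
        return self.temperature + CELSIUS_TO_KELVIN

    @property
    def time_min(self) -> np.ndarray:
        """Elapsed time (min) since the first grid point, t = (T - T0)/beta."""
        return (self.temperature - self.temperature[0]) / self.beta

    def with_heat_flow(self, heat_flow: np.ndarray) -> "Thermogram":
        return replace(self, heat_flow=np.asarray(heat_flow, dtype=float))


@dataclass(frozen=True)
class RheoSweep:
    """An oscillatory temperature sweep: storage and loss moduli (Pa, both
    strictly positive) on a strictly increasing temperature grid (°C), at a
    fixed oscillation frequency (Hz)."""

    temperature: np.ndarray
    storage_modulus: np.ndarray
    loss_modulus: np.ndarray
    frequency: float = 1.0
    sample_id: str = ""

    def __post_init__(self):
        t = _as_float_array(self.temperature, "temperature")
        gp = _as_float_array(self.storage_modulus, "storage_modulus")
        gpp = _as_float_array(self.loss_modulus, "loss_modulus")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "storage_modulus", gp)
        object.__setattr__(self, "loss_modulus", gpp)
        if not (t.size == gp.size == gpp.size):
            raise ValueError("temperature, G' and G'' must have equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("temperature must be strictly increasing")
        if np.any(gp <= 0) or np.any(gpp <= 0):
            raise ValueError("moduli must be strictly positive")
        if not self.frequency > 0:
            raise ValueError("frequency must be positive (Hz)")


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration shared by the pipeline stages.

    alpha_window is the conversion range used in the Coats-Redfern
    regression; smoothing_window / smoothing_order parameterize the
    Savitzky-Golay filter applied before peak and inflexion detection.
    """

    alpha_window: tuple[float, float] = (0.05, 0.95)
    candidate_models: tuple[str, ...] = ("F1", "F2")
    smoothing_window: int = 11
    smoothing_order: int = 3
    noise_seed: int = 0
    baseline_method: str = "linear"

    def __post_init__(self):
        lo, hi = self.alpha_window
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("alpha_window must satisfy 0 < lo < hi < 1")
        if self.smoothing_window % 2 != 1:
            raise ValueError("smoothing_window must be odd")
        if self.smoothing_window < self.smoothing_order + 2:
            raise ValueError("smoothing_window must be >= smoothing_order + 2")
        if not self.candidate_models:
            raise ValueError("candidate_models must be non-empty")
        if self.baseline_method != "linear":
            raise ValueError("only the 'linear' baseline method is implemented")

    def to_json(self, path) -> None:
        payload = {
            "alpha_window": list(self.alpha_window),
            "candidate_models": list(self.candidate_models),
            "smoothing_window": self.smoothing_window,
            "smoothing_order": self.smoothing_order,
            "noise_seed": self.noise_seed,
            "baseline_method": self.baseline_method,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload["alpha_window"] = tuple(payload["alpha_window"])
        payload["candidate_models"] = tuple(payload["candidate_models"])
        return cls(**payload)


def _read_numeric_csv(path, n_cols: int) -> np.ndarray:
    """Read an n-column numeric CSV, skipping a single non-numeric header row."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    start = 0
    first = lines[0].split(",")
    try:
        [float(v) for v in first]
    except ValueError:
        start = 1
    data = np.loadtxt(_io.StringIO("\n".join(lines[start:])), delimiter=",", ndmin=2)
    if data.shape[1] != n_cols:
        raise ValueError(f"{path}: expected {n_cols} columns, found {data.shape[1]}")
    return data


def read_thermogram(path, mass: float, beta: float, sample_id: str = "") -> Thermogram:
    """Read a two-column (temperature_C, heat_flow_mW) CSV into a Thermogram.

    Rows sharing a temperature are collapsed by averaging their heat flow.
    Fewer than 10 distinct rows, or a non-monotone grid after collapsing,
    is rejected.
    """
    data = _read_numeric_csv(path, 2)
    df = pd.DataFrame(data, columns=["temperature", "heat_flow"])
    df = df.groupby("temperature", sort=False, as_index=False).mean()
    t = df["temperature"].to_numpy()
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: temperature grid is not strictly increasing")
    if t.size < 10:
        raise ValueError(f"{path}: need at least 10 rows, found {t.size}")
    return Thermogram(t, df["heat_flow"].to_numpy(), mass=mass, beta=beta,
                      sample_id=sample_id or Path(path).stem)


def write_thermogram(tg: Thermogram, path) -> None:
    pd.DataFrame({"temperature_C": tg.temperature, "heat_flow_mW": tg.heat_flow}
                 ).to_csv(path, index=False, float_format="%.10g")


def read_rheo_sweep(path, frequency: float = 1.0, sample_id: str = "") -> RheoSweep:
    """Read a three-column (temperature_C, Gprime_Pa, Gdoubleprime_Pa) CSV."""
    data = _read_numeric_csv(path, 3)
    return RheoSweep(data[:, 0], data[:, 1], data[:, 2], frequency=frequency,
                     sample_id=sample_id or Path(path).stem)


def write_rheo_sweep(sweep: RheoSweep, path) -> None:
    pd.DataFrame({
        "temperature_C": sweep.temperature,
        "Gprime_Pa": sweep.storage_modulus,
        "Gdoubleprime_Pa": sweep.loss_modulus,
    }).to_csv(path, index=False, float_format="%.10g")


def write_kinetics_table(fits: Sequence[tuple], path) -> pd.DataFrame:
    """Write per-sample kinetic fits plus a per-peak average block.

    ``fits`` is a sequence of (sample_id, peak_number, KineticFit).  Output
    columns: sample, peak, Td_C, model, E_J_per_mol, A_per_min, r_squared.
    The appended average block reports, per peak, the arithmetic mean and
    sample standard deviation (n-1 denominator; 0 for a single value).
    """
    from .kinetics import aggregate_fits  # local import to avoid a cycle

    if not fits:
        raise ValueError("fits must be non-empty")
    rows = []
    for sample_id, peak_number, fit in fits:
        rows.append({
            "sample": sample_id,
            "peak": peak_number,
            "Td_C": fit.Td_C,
            "model": fit.model,
            "E_J_per_mol": fit.E,
            "A_per_min": fit.A,
            "r_squared": fit.r_squared,
        })
    table = pd.DataFrame(rows)
    agg = aggregate_fits(table)
    avg_rows = []
    for _, r in agg.iterrows():
        avg_rows.append({
            "sample": "average",
            "peak": r["peak"],
            "Td_C": r["Td_mean"],
            "model": r["model"],
            "E_J_per_mol": r["E_mean"],
            "A_per_min": r["A_mean"],
            "r_squared": np.nan,
        })
    out = pd.concat([table, pd.DataFrame(avg_rows)], ignore_index=True)
    out.to_csv(path, index=False, float_format="%.10g")
    return out
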