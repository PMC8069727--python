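"""Reference per-sample results for Baltic herring muscle tissue.

A published DSC study of Baltic herring (four samples A-D, four
denaturation transitions each: myosin, sarcoplasm, connective tissue,
actin) reports per-sample denaturation temperatures, selected kinetic
models and Arrhenius parameters, together with per-sample Spearman
correlations of perceptron surrogates.  The printed per-sample values
are carried here as a worked dataset for the aggregation and reporting
stages; the raw thermograms behind them are not publicly available.

Note: the printed (E, A) pairs are mutually inconsistent with the
printed peak temperatures under any standard non-isothermal rate law at
5 K/min (the magnitudes suggest E was tabulated in kJ/mol while A spans
1e5-1e16 1/min), so they are used here only as regression outputs to be
aggregated, never as simulation inputs.  Two printed per-peak average E
cells (peaks 2 and 3) do not equal the mean of their own per-sample
values; only the self-consistent cells are meaningful checks.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["herring_dsc_results", "herring_surrogate_results"]

_DSC_ROWS = [
    # sample, peak, Td_C, model, E (as printed), A (1/min)
    ("A", 1, 44.50, "F1", 244.46, 1.30e16),
    ("A", 2, 56.94, "F1", 125.36, 1.69e8),
    ("A", 3, 72.29, "F2", 116.67, 3.04e7),
    ("A", 4, 76.84, "F1", 183.65, 3.71e11),
    ("B", 1, 43.28, "F1", 92.53, 5.25e5),
    ("B", 2, 57.85, "F1", 86.43, 1.48e5),
    ("B", 3, 69.09, "F2", 191.51, 1.43e12),
    ("B", 4, 78.79, "F1", 97.11, 1.19e6),
    ("C", 1, 42.35, "F1", 90.33, 2.93e5),
    ("C", 2, 57.13, "F1", 223.93, 4.13e14),
    ("C", 3, 66.91, "F2", 115.22, 3.04e7),
    ("C", 4, 77.87, "F1", 106.42, 5.23e6),
    ("D", 1, 43.66, "F1", 183.60, 3.70e11),
    ("D", 2, 55.26, "F1", 92.72, 5.48e5),
    ("D", 3, 67.76, "F2", 86.40, 1.47e5),
    ("D", 4, 78.13, "F1", 245.16, 1.20e16),
]

_SURROGATE_ROWS = [
    ("A", 1, 24, 0.998), ("A", 2, 32, 0.989), ("A", 3, 36, 0.973), ("A", 4, 24, 0.998),
    ("B", 1, 45, 0.976), ("B", 2, 31, 0.969), ("B", 3, 32, 0.983), ("B", 4, 24, 0.958),
    ("C", 1, 21, 0.979), ("C", 2, 29, 0.972), ("C", 3, 53, 0.993), ("C", 4, 25, 0.981),
    ("D", 1, 21, 0.989), ("D", 2, 25, 0.999), ("D", 3, 24, 0.988), ("D", 4, 34, 0.978),
]


def herring_dsc_results() -> pd.DataFrame:
    """Per-sample DSC kinetics results in the package results schema
    (columns sample, peak, Td_C, model, E_J_per_mol, A_per_min)."""
    return pd.DataFrame(_DSC_ROWS, columns=[
        "sample", "peak", "Td_C", "model", "E_J_per_mol", "A_per_min"])


def herring_surrogate_results() -> pd.DataFrame:
    """Per-sample perceptron surrogate quality (hidden-unit counts and
    Spearman R between experimental and model conversion curves)."""
    return pd.DataFrame(_SURROGATE_ROWS, columns=[
        "sample", "peak", "hidden_units", "spearman_R"])
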