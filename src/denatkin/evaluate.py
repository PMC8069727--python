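"""Agreement between experimental and model conversion curves.

The headline statistic is Spearman's rank correlation between the
experimental alpha(T) and the curve reconstructed from the fitted
kinetics.  A single-hidden-layer perceptron surrogate (1 input
temperature, tanh hidden layer, linear output, quasi-Newton training)
is available as an alternative smooth representation of a conversion
curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .kinetics import ConversionCurve

__all__ = ["spearman_r", "SurrogateModel", "fit_surrogate", "compare_curves"]


def spearman_r(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks
    (ties receive their average rank).

    Rejects sequences shorter than 3 and constant input, whose rank
    variance is zero and for which the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant input: rank variance is zero, "
                         "Spearman correlation is undefined")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


@dataclass(frozen=True)
class SurrogateModel:
    """A trained 1-H-1 perceptron surrogate of a conversion curve."""

    hidden_units: int
    seed: int
    training_error: float          # MSE on the training grid
    converged: bool
    predictions: np.ndarray        # on the training grid
    _mlp: object = None
    _x_mean: float = 0.0
    _x_scale: float = 1.0

    def predict(self, temperature_K) -> np.ndarray:
        x = (np.asarray(temperature_K, dtype=float).reshape(-1, 1)
             - self._x_mean) / self._x_scale
        return self._mlp.predict(x)


def fit_surrogate(curve: ConversionCurve, hidden_units: int = 24,
                  seed: int = 0, max_iter: int = 500) -> SurrogateModel:
    """Train a 1:H:1 perceptron (tanh hidden layer, identity output) on
    alpha versus standardized temperature by the quasi-Newton L-BFGS
    minimizer of the mean squared error.

    Deterministic for a fixed (seed, data, settings) triple.  A model
    that exhausts ``max_iter`` without meeting the tolerance is returned
    with ``converged=False`` rather than raised.
    """
    from sklearn.neural_network import MLPRegressor

    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    if curve.temperature.size < 20:
        raise ValueError("need at least 20 points to fit a surrogate")

    x = curve.temperature.reshape(-1, 1)
    x_mean = float(x.mean())
    x_scale = float(x.std())
    if x_scale == 0:
        raise ValueError("temperature grid is degenerate")
    xs = (x - x_mean) / x_scale

    mlp = MLPRegressor(hidden_layer_sizes=(hidden_units,), activation="tanh",
                       solver="lbfgs", alpha=0.0, max_iter=max_iter,
                       tol=1e-10, random_state=seed)
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        mlp.fit(xs, curve.alpha)
    pred = mlp.predict(xs)
    mse = float(np.mean((pred - curve.alpha) ** 2))
    converged = mlp.n_iter_ < max_iter
    return SurrogateModel(hidden_units=hidden_units, seed=seed,
                          training_error=mse, converged=converged,
                          predictions=pred, _mlp=mlp,
                          _x_mean=x_mean, _x_scale=x_scale)


def compare_curves(exp: ConversionCurve, model: ConversionCurve
                   ) -> tuple[float, float]:
    """(Spearman R, max |deviation|) between an experimental curve and a
    model curve; the model curve is linearly interpolated onto the
    experimental grid when the grids differ."""
    t = exp.temperature
    if model.temperature[0] > t[-1] or model.temperature[-1] < t[0]:
        raise ValueError("curves cover disjoint temperature ranges")
    if (model.temperature.size == t.size
            and np.allclose(model.temperature, t, rtol=0, atol=1e-9)):
        pred = model.alpha
    else:
        lo = np.searchsorted(t, model.temperature[0], side="left")
        hi = np.searchsorted(t, model.temperature[-1], side="right")
        t = t[lo:hi]
        if t.size < 3:
            raise ValueError("temperature overlap is too short to compare")
        pred = np.interp(t, model.temperature, model.alpha)
        exp = ConversionCurve(t, exp.alpha[lo:hi], stage=exp.stage)
    rho = spearman_r(exp.alpha, pred)
    return rho, float(np.max(np.abs(exp.alpha - pred)))
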