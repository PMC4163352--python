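"""Linear forecaster: regression on lagged smoothed inputs with MA errors.

The model is x_hat(t) = sum_i alpha_i z_i(t) + sum_i beta_i e(t-i), where z
is the lag vector supplied by a :class:`~smoothcast.lagspace.RegressorSet`
and e are past one-step errors. With Q = 0 this is ordinary least squares;
with Q > 0 the coefficients minimise the conditional sum of squares, seeded
by a Hannan-Rissanen two-stage regression. Optional differencing of the
target series is provided separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .errors import DimensionError, FitError, LengthError
from .lagspace import RegressorSet
from .series import TimeSeries

__all__ = ["ArimaSpec", "ArimaFit", "difference", "undifference_forecast",
           "fit_linear_ma", "forecast_one_step"]


@dataclass(frozen=True)
class ArimaSpec:
    """Orders (P, D, Q): AR-term lags, differencing, MA-term lags."""

    P: int
    D: int = 0
    Q: int = 0

    def __post_init__(self):
        if self.P < 1 or self.D < 0 or self.Q < 0:
            raise ValueError(f"invalid orders P={self.P}, D={self.D}, Q={self.Q}")


@dataclass(frozen=True)
class ArimaFit:
    alpha: np.ndarray  # regressor coefficients, length K
    beta: np.ndarray  # MA coefficients, length Q
    residuals: np.ndarray  # in-sample one-step errors
    css: float  # conditional sum of squares at the optimum

    @property
    def K(self) -> int:
        return int(self.alpha.size)

    @property
    def Q(self) -> int:
        return int(self.beta.size)


def difference(x: TimeSeries | np.ndarray, d: int) -> np.ndarray:
    """Iterated first differences; output length n - d."""
    v = x.values if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)
    if d < 0:
        raise ValueError("differencing order must be non-negative")
    if d >= v.size:
        raise LengthError(f"cannot difference length-{v.size} series {d} times")
    return np.diff(v, n=d)


def undifference_forecast(pred_diff: float, history: np.ndarray, d: int) -> float:
    """Invert d-fold differencing of a one-step forecast given the raw history."""
    if d == 0:
        return float(pred_diff)
    value = float(pred_diff)
    h = np.asarray(history, dtype=float)
    for j in range(d, 0, -1):
        tail = np.diff(h, n=j - 1)
        value += tail[-1]
    return value


def _css_residuals(alpha: np.ndarray, beta: np.ndarray, Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    # e(t) + sum_i beta_i e(t-i) = y(t) - Z(t) @ alpha  -> IIR filter, zero init
    y_lin = y - Z @ alpha
    if beta.size == 0:
        return y_lin
    with np.errstate(over="ignore", invalid="ignore"):
        e = lfilter([1.0], np.concatenate([[1.0], beta]), y_lin)
    # a non-invertible beta makes the recursion explode; cap so the optimiser
    # sees a huge-but-finite cost and backs away from that region
    return np.nan_to_num(e, nan=1e100, posinf=1e100, neginf=-1e100)


def _shrink_to_invertible(beta: np.ndarray, margin: float = 0.95) -> np.ndarray:
    """Scale MA coefficients so the error recursion is stable at the start."""
    if beta.size == 0 or not np.all(np.isfinite(beta)):
        return np.zeros_like(beta)
    roots = np.roots(np.concatenate([[1.0], beta]))
    if roots.size == 0:
        return beta
    r = np.max(np.abs(roots))
    if r < margin:
        return beta
    c = margin / r
    return beta * c ** np.arange(1, beta.size + 1)


def fit_linear_ma(train: RegressorSet, spec: ArimaSpec, tol: float = 1e-8,
                  max_iter: int = 500) -> ArimaFit:
    """Estimate alpha, beta by conditional sum of squares.

    Q = 0 reduces exactly to least squares on the regressors. For Q > 0 the
    start point is the Hannan-Rissanen regression (OLS residuals re-entered
    as lagged regressors) refined by Levenberg-Marquardt on the CSS
    objective. Deterministic: no randomness is involved.
    """
    Z = np.asarray(train.rows, dtype=float)
    y = np.asarray(train.targets, dtype=float)
    n, K = Z.shape
    Q = spec.Q
    if n < K + Q + 5:
        raise FitError(f"need at least K+Q+5={K + Q + 5} rows, got {n}")

    if np.linalg.matrix_rank(Z) < K:
        warnings.warn("rank-deficient regressor matrix; using pseudo-inverse solution",
                      RuntimeWarning, stacklevel=2)
    alpha0, *_ = np.linalg.lstsq(Z, y, rcond=None)

    if Q == 0:
        resid = y - Z @ alpha0
        return ArimaFit(alpha0, np.zeros(0), resid, float(resid @ resid))

    # Hannan-Rissanen: regress on [Z, lagged OLS residuals] for a start point
    e0 = y - Z @ alpha0
    E = np.zeros((n, Q))
    for i in range(1, Q + 1):
        E[i:, i - 1] = e0[:-i]
    design = np.hstack([Z, E])
    theta0, *_ = np.linalg.lstsq(design, y, rcond=None)
    x0 = np.concatenate([theta0[:K], _shrink_to_invertible(theta0[K:])])

    def resid_fn(theta):
        return _css_residuals(theta[:K], theta[K:], Z, y)

    sol = least_squares(resid_fn, x0, method="lm", xtol=tol, ftol=tol, gtol=tol,
                        max_nfev=max_iter * (K + Q + 1))
    if not np.all(np.isfinite(sol.x)):
        raise FitError(f"CSS optimisation diverged: status={sol.status}, nfev={sol.nfev}")
    alpha, beta = sol.x[:K], sol.x[K:]
    resid = _css_residuals(alpha, beta, Z, y)
    return ArimaFit(alpha, beta, resid, float(resid @ resid))


def forecast_one_step(fit: ArimaFit, test: RegressorSet,
                      error_history: np.ndarray | None = None) -> np.ndarray:
    """Teacher-forced one-step-ahead forecasts over the test rows, in order.

    The MA error history starts from the training residuals (or
    ``error_history`` if given, possibly empty) and is extended with the
    observed test errors as forecasting proceeds.
    """
    Z = np.asarray(test.rows, dtype=float)
    if Z.shape[1] != fit.K:
        raise DimensionError(f"regressor width {Z.shape[1]} != fitted width {fit.K}")
    y = np.asarray(test.targets, dtype=float)
    Q = fit.Q
    if Q == 0:
        return Z @ fit.alpha
    hist = list(fit.residuals if error_history is None else np.asarray(error_history, dtype=float))
    preds = np.empty(y.size)
    base = Z @ fit.alpha
    for t in range(y.size):
        ma = sum(fit.beta[i - 1] * hist[-i] for i in range(1, Q + 1) if i <= len(hist))
        preds[t] = base[t] + ma
        hist.append(y[t] - preds[t])
    return preds
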