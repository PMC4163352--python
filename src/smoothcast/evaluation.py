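"""Forecast accuracy metrics, residual ACF diagnostics and Pitman's test.

Metrics: RMSE, GCV = RMSE / (1 - K/Nv)^2, MAPE (percent) and per-point
relative errors. Pitman's test compares the error variances of two
forecasters by testing whether corr(e1 + e2, e1 - e2) differs from zero;
|corr| above 1.96 / sqrt(Nv) is significant at the 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, LengthError, UndefinedMetricError

__all__ = [
    "ForecastResult",
    "MetricsReport",
    "AcfReport",
    "PitmanComparison",
    "forecast_metrics",
    "acf_with_bounds",
    "pitman_threshold",
    "pitman_test",
]


@dataclass(frozen=True)
class ForecastResult:
    """Observed/predicted pairs on the test window, plus the regressor width K."""

    observed: np.ndarray
    predicted: np.ndarray
    K: int

    def __post_init__(self):
        obs = np.asarray(self.observed, dtype=float)
        pred = np.asarray(self.predicted, dtype=float)
        if obs.size != pred.size:
            raise LengthError("observed and predicted lengths differ")
        if obs.size < 2:
            raise LengthError("need at least 2 test points")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "predicted", pred)

    @property
    def errors(self) -> np.ndarray:
        return self.observed - self.predicted

    @property
    def nv(self) -> int:
        return int(self.observed.size)


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    gcv: float
    mape_percent: float
    re_series: np.ndarray
    re_sum: float


@dataclass(frozen=True)
class AcfReport:
    """Sample autocorrelations for lags 0..max_lag with 95% bands."""

    coefficients: np.ndarray  # index = lag, coefficients[0] == 1
    conf_limit: float
    white: bool


@dataclass(frozen=True)
class PitmanComparison:
    corr: float
    threshold: float
    significant: bool
    winner: int | None  # 1, 2 or None
    degenerate: bool = False


def forecast_metrics(fr: ForecastResult) -> MetricsReport:
    """RMSE, GCV, MAPE and relative errors for a one-step-ahead forecast."""
    e = fr.errors
    nv = fr.nv
    if fr.K >= nv:
        raise DataError(f"GCV undefined: K={fr.K} >= Nv={nv}")
    rmse = float(np.sqrt(np.mean(e**2)))
    gcv = rmse / (1.0 - fr.K / nv) ** 2
    zeros = np.flatnonzero(fr.observed == 0.0)
    if zeros.size:
        raise UndefinedMetricError(
            f"MAPE/RE undefined: zero observations at indices {zeros.tolist()}",
            indices=zeros,
        )
    re = e / fr.observed
    mape = float(np.mean(np.abs(re)) * 100.0)
    return MetricsReport(rmse, gcv, mape, re, float(np.sum(re)))


def acf_with_bounds(residuals: np.ndarray, max_lag: int) -> AcfReport:
    """Sample ACF (biased, divide-by-N normalisation) with +-1.96/sqrt(N) bands."""
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n <= max_lag:
        raise LengthError(f"need N > max_lag, got N={n}, max_lag={max_lag}")
    centred = r - r.mean()
    var = float(centred @ centred)
    if var == 0.0:
        raise DataError("ACF undefined for zero-variance residuals")
    rho = np.array([centred[: n - k] @ centred[k:] / var for k in range(max_lag + 1)])
    limit = 1.96 / np.sqrt(n)
    white = bool(np.all(np.abs(rho[1:]) <= limit))
    return AcfReport(rho, limit, white)


def pitman_threshold(nv: int) -> float:
    """5% two-sided significance threshold for the test correlation."""
    if nv < 1:
        raise DataError("test sample size must be positive")
    return float(1.96 / np.sqrt(nv))


def pitman_test(e1: np.ndarray, e2: np.ndarray) -> PitmanComparison:
    """Pairwise comparison of forecast-error variances.

    Negative correlation of (e1 + e2, e1 - e2) means model 1 has the
    smaller error variance. Identical error variances make the test
    degenerate; that case is flagged rather than raised.
    """
    a = np.asarray(e1, dtype=float)
    b = np.asarray(e2, dtype=float)
    if a.size != b.size:
        raise LengthError("error vectors must have equal lengths")
    if a.size < 3:
        raise LengthError("need at least 3 test points")
    nv = a.size
    upsilon = a + b
    psi = a - b
    threshold = pitman_threshold(nv)
    su = np.std(upsilon)
    sp = np.std(psi)
    if su == 0.0 or sp == 0.0:
        return PitmanComparison(float("nan"), threshold, False, None, degenerate=True)
    corr = float(np.corrcoef(upsilon, psi)[0, 1])
    significant = bool(abs(corr) > threshold)
    winner = None
    if significant:
        winner = 1 if corr < 0 else 2
    return PitmanComparison(corr, threshold, significant, winner)
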