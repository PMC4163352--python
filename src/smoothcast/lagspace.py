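"""Lagged regressor construction, min-max scaling and chronological splits.

Regressor rows contain only values strictly before their target period, so
one-step-ahead evaluation never leaks future information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LengthError, ScalingError, SplitError
from .series import TimeSeries
from .smoothing import SmoothedSeries

__all__ = [
    "RegressorSet",
    "ScalingParams",
    "SplitSpec",
    "scale_minmax",
    "build_regressors_ma",
    "build_regressors_hsvd",
    "split_train_test",
]


@dataclass(frozen=True)
class RegressorSet:
    """Matrix of lag vectors z(t) paired with targets x(t).

    ``t_index[r]`` is the 1-based period of ``targets[r]`` in the source
    series; row ``r`` holds lags ``t-1, t-2, ...`` in that order.
    """

    rows: np.ndarray  # (n_rows, K)
    targets: np.ndarray  # (n_rows,)
    t_index: np.ndarray  # (n_rows,)

    def __post_init__(self):
        if self.rows.shape[0] != self.targets.size or self.targets.size != self.t_index.size:
            raise LengthError("rows, targets and t_index must have equal counts")

    @property
    def K(self) -> int:
        return int(self.rows.shape[1])

    @property
    def n_rows(self) -> int:
        return int(self.rows.shape[0])


@dataclass(frozen=True)
class ScalingParams:
    """Affine min-max map fitted on (part of) a series; no clipping."""

    min: float
    max: float

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.min) / (self.max - self.min)

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * (self.max - self.min) + self.min


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float
    n_train: int
    n_test: int


def scale_minmax(x: TimeSeries, fit_count: int | None = None):
    """Scale a series to [0, 1] using the extremes of its first ``fit_count``
    points (defaults to all of them). Values outside the fitted range map
    outside [0, 1]; there is no clipping.

    Returns ``(scaled_series, params)``.
    """
    v = x.values
    k = v.size if fit_count is None else int(fit_count)
    if not 1 <= k <= v.size:
        raise ScalingError(f"fit_count must be in [1, n], got {k}")
    lo, hi = float(np.min(v[:k])), float(np.max(v[:k]))
    if hi <= lo:
        raise ScalingError("cannot min-max scale a constant series")
    params = ScalingParams(lo, hi)
    return x.with_values(params.transform(v)), params


def _as_array(s) -> np.ndarray:
    if isinstance(s, (TimeSeries, SmoothedSeries)):
        return s.values
    return np.asarray(s, dtype=float)


def _lag_matrix(v: np.ndarray, K: int) -> np.ndarray:
    # row for target t (1-based, t = K+1..n) holds v[t-2], v[t-3], ... v[t-K-1] in 0-based terms
    n = v.size
    t0 = np.arange(K, n)  # 0-based target positions
    lags = t0[:, None] - np.arange(1, K + 1)[None, :]
    return v[lags]


def build_regressors_ma(smoothed, x: TimeSeries, K: int) -> RegressorSet:
    """Rows of K lags of the smoothed series, targets from the raw series."""
    s = _as_array(smoothed)
    xv = _as_array(x)
    n = xv.size
    if s.size != n:
        raise LengthError("smoothed series and target series lengths differ")
    if not 1 <= K < n:
        raise LengthError(f"need 1 <= K < n, got K={K}, n={n}")
    rows = _lag_matrix(s, K)
    t_index = np.arange(K + 1, n + 1)
    return RegressorSet(rows, xv[K:], t_index)


def build_regressors_hsvd(c_low, c_high, x: TimeSeries, P: int, mode: str = "both_components") -> RegressorSet:
    """Lag vectors from the low/high HSVD components.

    ``mode='both_components'`` (default): P lags of each component, width
    K = 2P. ``mode='shared'``: P lags of the low-frequency component only,
    width K = P (the narrower network-input reading).
    """
    cl = _as_array(c_low)
    ch = _as_array(c_high)
    xv = _as_array(x)
    n = xv.size
    if cl.size != n or ch.size != n:
        raise LengthError("component and target series lengths differ")
    if not 1 <= P < n:
        raise LengthError(f"need 1 <= P < n, got P={P}, n={n}")
    if mode == "both_components":
        rows = np.hstack([_lag_matrix(cl, P), _lag_matrix(ch, P)])
    elif mode == "shared":
        rows = _lag_matrix(cl, P)
    else:
        raise ValueError(f"unknown hsvd lag mode: {mode!r}")
    t_index = np.arange(P + 1, n + 1)
    return RegressorSet(rows, xv[P:], t_index)


def split_train_test(rs: RegressorSet, train_fraction: float):
    """Chronological split: first floor(fraction * rows) rows train, rest test."""
    if not 0.0 < train_fraction < 1.0:
        raise SplitError(f"train fraction must be in (0, 1), got {train_fraction}")
    n = rs.n_rows
    n_train = int(np.floor(train_fraction * n))
    if n_train < 1 or n - n_train < 1:
        raise SplitError(f"split leaves an empty partition (rows={n}, fraction={train_fraction})")
    train = RegressorSet(rs.rows[:n_train], rs.targets[:n_train], rs.t_index[:n_train])
    test = RegressorSet(rs.rows[n_train:], rs.targets[n_train:], rs.t_index[n_train:])
    return train, test
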