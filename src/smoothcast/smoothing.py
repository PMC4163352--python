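"""Smoothing front-ends for the forecasters.

Two strategies are provided:

* ``moving_average_3`` — centred 3-point moving average with endpoint
  copying; a linear low-pass filter that extracts the trend.
* ``hsvd_decompose`` — embed the series into a Hankel trajectory matrix,
  take its SVD and reassemble one additive component per singular value
  from the first row and last column of each rank-one term. Component 1 is
  the low-frequency part ``C_L``; components ``2..M`` sum to the
  high-frequency part ``C_H``, and ``C_L + C_H`` reconstructs the series
  exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DimensionError, LengthError
from .series import TimeSeries

__all__ = [
    "SmoothedSeries",
    "HankelMatrix",
    "HsvdResult",
    "moving_average_3",
    "build_hankel",
    "hsvd_decompose",
    "component_energy",
]


@dataclass(frozen=True)
class SmoothedSeries:
    """Smoothed values, same length as the source series."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class HankelMatrix:
    """Trajectory matrix with entry(i, j) = x_{i+j-1} (1-based)."""

    entries: np.ndarray

    @property
    def M(self) -> int:
        return self.entries.shape[0]

    @property
    def L(self) -> int:
        return self.entries.shape[1]


@dataclass(frozen=True)
class HsvdResult:
    """Additive decomposition of a series into per-singular-value components.

    ``components[i]`` has the length of the source series; ``low`` is
    ``components[0]`` and ``high`` the sum of the rest. ``energies`` is
    ``None`` for an identically zero series (energy undefined).
    """

    components: np.ndarray  # (n_components, n)
    singular_values: np.ndarray
    energies: np.ndarray | None
    low: np.ndarray
    high: np.ndarray


def moving_average_3(x: TimeSeries | np.ndarray) -> SmoothedSeries:
    """Centred 3-point moving average; endpoints copy the source values."""
    v = x.values if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)
    if v.size < 3:
        raise LengthError(f"3-point moving average needs n >= 3, got n={v.size}")
    if not np.all(np.isfinite(v)):
        raise DataError("series contains non-finite values")
    out = v.copy()
    out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    return SmoothedSeries(out)


def build_hankel(x: TimeSeries | np.ndarray, M: int) -> HankelMatrix:
    """Embed the series into its M x L Hankel trajectory matrix, L = n - M + 1."""
    v = x.values if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)
    n = v.size
    if not 1 <= M < n:
        raise DimensionError(f"Hankel order must satisfy 1 <= M < n, got M={M}, n={n}")
    L = n - M + 1
    idx = np.arange(M)[:, None] + np.arange(L)[None, :]
    return HankelMatrix(v[idx])


def _extract_component(A: np.ndarray) -> np.ndarray:
    # first row, then rows 2..M of the last column: length L + (M-1) = n
    return np.concatenate([A[0, :], A[1:, -1]])


def hsvd_decompose(x: TimeSeries | np.ndarray, M: int) -> HsvdResult:
    """Hankel-SVD decomposition into additive components of length n.

    Produces ``min(M, L)`` components (the Hankel matrix has at most that
    many singular triplets); with the default M = 2 there are exactly two.
    """
    v = x.values if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)
    n = v.size
    if not 2 <= M < n:
        raise DimensionError(f"HSVD requires 2 <= M < n, got M={M}, n={n}")
    H = build_hankel(v, M).entries
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    # sign convention: largest-magnitude entry of each left vector positive
    for i in range(s.size):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            Vt[i, :] = -Vt[i, :]
    comps = np.empty((s.size, n))
    for i in range(s.size):
        A_i = s[i] * np.outer(U[:, i], Vt[i, :])
        comps[i] = _extract_component(A_i)
    energies = component_energy(s) if np.any(s > 0) else None
    low = comps[0]
    high = comps[1:].sum(axis=0)
    return HsvdResult(comps, s, energies, low, high)


def component_energy(singular_values: np.ndarray) -> np.ndarray:
    """Share of squared spectrum per component: E_i = s_i^2 / sum_j s_j^2."""
    s = np.asarray(singular_values, dtype=float)
    total = float(np.sum(s**2))
    if total <= 0.0:
        raise DataError("component energy undefined: all singular values are zero")
    return s**2 / total
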