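"""Univariate time-series container and CSV I/O.

A :class:`TimeSeries` is an ordered vector of finite real values with
optional, strictly increasing period labels (integer indices or ISO dates).
CSV files are UTF-8, comma-delimited, ``.`` decimal separator, with header
``period,value`` (the ``period`` column is optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, LengthError

__all__ = ["TimeSeries", "read_series_csv", "write_series_csv"]


@dataclass(frozen=True)
class TimeSeries:
    """Ordered real values ``x_1..x_n`` with optional period labels."""

    values: np.ndarray
    labels: tuple | None = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise DataError(f"series must be 1-D, got shape {values.shape}")
        if values.size < 1:
            raise LengthError("series must contain at least one value")
        if not np.all(np.isfinite(values)):
            bad = np.flatnonzero(~np.isfinite(values))
            raise DataError(f"non-finite values at positions {bad.tolist()}")
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != values.size:
                raise DataError("labels length does not match values length")
            if any(b <= a for a, b in zip(labels, labels[1:])):
                raise DataError("period labels must be strictly increasing")
            object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.values)

    def with_values(self, values: Sequence[float]) -> "TimeSeries":
        """New series with the same labels (if lengths agree) and new values."""
        values = np.asarray(values, dtype=float)
        labels = self.labels if self.labels is not None and len(self.labels) == values.size else None
        return TimeSeries(values, labels)


def read_series_csv(path: str | Path) -> TimeSeries:
    """Read a ``period,value`` (or single ``value`` column) CSV file."""
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot read series from {path}: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    if "value" not in cols:
        raise DataError(f"{path}: expected a 'value' column, found {list(df.columns)}")
    try:
        values = df[cols["value"]].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: non-numeric values: {exc}") from exc
    labels = None
    if "period" in cols:
        labels = tuple(df[cols["period"]].tolist())
    return TimeSeries(values, labels)


def write_series_csv(ts: TimeSeries, path: str | Path) -> None:
    """Write a series as a ``period,value`` CSV file."""
    periods = ts.labels if ts.labels is not None else range(1, ts.n + 1)
    pd.DataFrame({"period": list(periods), "value": ts.values}).to_csv(
        path, index=False, encoding="utf-8"
    )
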