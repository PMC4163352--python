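"""Seeded generators for test and benchmark series.

``generate_accident_series`` emulates a weekly surveillance count signal:
positive level, slow smooth trend, annual-period sinusoid and irregular
high-frequency noise. ``generate_arma_series`` produces standard ARMA
realisations used as parameter-recovery oracles for the linear forecaster.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigError
from .series import TimeSeries

__all__ = [
    "AccidentSeriesConfig",
    "ArmaConfig",
    "generate_accident_series",
    "generate_arma_series",
]


@dataclass(frozen=True)
class AccidentSeriesConfig:
    n: int = 531
    base: float = 50.0
    trend_amp: float = 15.0
    seas_period: int = 52
    seas_amp: float = 8.0
    noise_sd: float = 4.0
    noise: str = "gaussian"  # or "poisson"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ArmaConfig:
    alpha: tuple = ()
    beta: tuple = ()
    noise_sd: float = 1.0
    n: int = 1000
    burn_in: int = 200
    seed: int = 0


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def deterministic_part(cfg: AccidentSeriesConfig) -> np.ndarray:
    t = np.arange(1, cfg.n + 1)
    trend = cfg.trend_amp * _smoothstep(t / cfg.n)
    seasonal = cfg.seas_amp * np.sin(2.0 * np.pi * t / cfg.seas_period)
    return cfg.base + trend + seasonal


def generate_accident_series(cfg: AccidentSeriesConfig) -> TimeSeries:
    """Positive trend + seasonal + noise series, reproducible per seed."""
    if cfg.n < 3:
        raise ConfigError("series length must be at least 3")
    if cfg.trend_amp < 0 or cfg.seas_amp < 0 or cfg.noise_sd < 0:
        raise ConfigError("amplitudes must be non-negative")
    det = deterministic_part(cfg)
    # guard: 6-sigma margin keeps Gaussian realisations strictly positive
    if det.min() - 6.0 * cfg.noise_sd <= 0:
        raise ConfigError(
            f"config admits non-positive values: deterministic min {det.min():.3f}, "
            f"noise sd {cfg.noise_sd}"
        )
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise == "gaussian":
        values = det + rng.normal(0.0, cfg.noise_sd, cfg.n)
    elif cfg.noise == "poisson":
        values = rng.poisson(det).astype(float)
        values = np.maximum(values, 1.0)  # counts of 0 would break MAPE
    else:
        raise ConfigError(f"unknown noise model: {cfg.noise!r}")
    if np.any(values <= 0):
        raise ConfigError("generated series is not strictly positive; reduce noise_sd")
    return TimeSeries(values)


def _check_stationary(alpha: tuple) -> None:
    if not alpha:
        return
    p = len(alpha)
    # roots of z^p - a1 z^{p-1} - ... - ap must lie inside the unit circle
    poly = np.concatenate([[1.0], -np.asarray(alpha, dtype=float)])
    roots = np.roots(poly)
    if np.any(np.abs(roots) >= 1.0):
        raise ConfigError(f"non-stationary AR coefficients {alpha}")


def generate_arma_series(cfg: ArmaConfig) -> TimeSeries:
    """ARMA(p, q) recursion x_t = sum a_i x_{t-i} + e_t + sum b_i e_{t-i}."""
    _check_stationary(tuple(cfg.alpha))
    if cfg.n < 1 or cfg.burn_in < 0:
        raise ConfigError("invalid length or burn-in")
    rng = np.random.default_rng(cfg.seed)
    p, q = len(cfg.alpha), len(cfg.beta)
    total = cfg.n + cfg.burn_in
    e = rng.normal(0.0, cfg.noise_sd, total)
    x = np.zeros(total)
    for t in range(total):
        ar = sum(cfg.alpha[i] * x[t - 1 - i] for i in range(p) if t - 1 - i >= 0)
        ma = sum(cfg.beta[i] * e[t - 1 - i] for i in range(q) if t - 1 - i >= 0)
        x[t] = ar + ma + e[t]
    return TimeSeries(x[cfg.burn_in:])
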