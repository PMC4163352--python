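"""End-to-end experiment orchestration.

Runs every requested (smoothing x forecaster) combination on one series:
scale -> smooth/decompose -> lagged regressors -> chronological split ->
fit (with optional GCV-driven selection of the MA order, and best-of-N
seeded repetitions for the stochastic trainers) -> one-step-ahead test
forecast -> metrics, residual ACF and the pairwise Pitman comparison
matrix. Everything is reproducible from (config, seed_base).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ann import PsoConfig, RpropConfig, ann_forward_batch, train_pso, train_rprop
from .arima import ArimaSpec, fit_linear_ma, forecast_one_step
from .errors import ConfigError, FitError
from .evaluation import ForecastResult, acf_with_bounds, forecast_metrics, pitman_test
from .lagspace import RegressorSet, build_regressors_hsvd, build_regressors_ma, scale_minmax, split_train_test
from .series import TimeSeries, read_series_csv
from .smoothing import hsvd_decompose, moving_average_3
from .synthetic import AccidentSeriesConfig, generate_accident_series

__all__ = ["ExperimentConfig", "gcv_scan", "run_experiment"]

_SMOOTHINGS = ("ma3", "hsvd")
_MODELS = ("arima", "ann-pso", "ann-rprop")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    input: str | None = None
    synthetic: dict | None = None
    smoothings: tuple = _SMOOTHINGS
    models: tuple = _MODELS
    P: int = 9
    D: int = 0
    M: int = 2
    arima_q: dict = field(default_factory=lambda: {"ma3": 10, "hsvd": 11})
    q_scan: tuple | None = None  # (lo, hi) -> GCV scan replaces arima_q
    hidden: dict = field(default_factory=lambda: {"ma3": 10, "hsvd": 11})
    runs: int = 30
    seed_base: int = 42
    train_fraction: float = 0.85
    scaling: str = "minmax"
    hsvd_lag_mode: str = "both_components"
    original_scale: bool = False
    pso: dict = field(default_factory=dict)
    rprop: dict = field(default_factory=dict)

    def __post_init__(self):
        self.smoothings = tuple(self.smoothings)
        self.models = tuple(self.models)
        for s in self.smoothings:
            if s not in _SMOOTHINGS:
                raise ConfigError(f"unknown smoothing id {s!r}; choose from {_SMOOTHINGS}")
        for m in self.models:
            if m not in _MODELS:
                raise ConfigError(f"unknown model id {m!r}; choose from {_MODELS}")
        if not self.models or not self.smoothings:
            raise ConfigError("need at least one smoothing and one model")
        if self.input is None and self.synthetic is None:
            raise ConfigError("provide either an input CSV or a synthetic config")
        if self.scaling not in ("minmax", "none"):
            raise ConfigError(f"unknown scaling {self.scaling!r}")
        if self.q_scan is not None:
            lo, hi = self.q_scan
            if not 1 <= lo <= hi <= 30:
                raise ConfigError("q_scan must lie within [1, 30]")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _int_keys(d: dict, name: str, smoothing: str) -> int:
    if isinstance(d, dict):
        if smoothing not in d:
            raise ConfigError(f"{name} has no entry for smoothing {smoothing!r}")
        return int(d[smoothing])
    return int(d)


def gcv_scan(train: RegressorSet, fit_forecast, q_range, holdout_fraction: float = 0.15):
    """Choose a model order Q by GCV on a chronological tail of the training rows.

    ``fit_forecast(q, inner_train, inner_holdout)`` must return predictions
    for the holdout rows. The GCV penalty uses the effective coefficient
    count K + q. Returns ``(chosen_q, table)`` where the table maps each q
    to its holdout GCV; ties break toward the smaller q.
    """
    qs = list(q_range)
    if not qs:
        raise ConfigError("empty Q range")
    inner_train, inner_hold = split_train_test(train, 1.0 - holdout_fraction)
    nv = inner_hold.n_rows
    table = {}
    failures = []
    for q in qs:
        try:
            preds = fit_forecast(q, inner_train, inner_hold)
            e = inner_hold.targets - preds
            rmse = float(np.sqrt(np.mean(e**2)))
            k_eff = train.K + q
            if k_eff >= nv:
                raise FitError(f"GCV undefined for q={q}: K+q={k_eff} >= holdout {nv}")
            table[q] = rmse / (1.0 - k_eff / nv) ** 2
        except FitError as exc:
            failures.append((q, str(exc)))
            table[q] = float("nan")
    finite = {q: g for q, g in table.items() if np.isfinite(g)}
    if not finite:
        raise FitError(f"all fits in the GCV scan failed: {failures}")
    chosen = min(finite, key=lambda q: (finite[q], q))
    return chosen, table


def _load_series(cfg: ExperimentConfig) -> TimeSeries:
    if cfg.input is not None:
        return read_series_csv(cfg.input)
    syn = dict(cfg.synthetic)
    syn.setdefault("seed", cfg.seed_base)
    return generate_accident_series(AccidentSeriesConfig(**syn))


def _build_regressors(cfg: ExperimentConfig, smoothing: str, x: TimeSeries) -> RegressorSet:
    if smoothing == "ma3":
        s = moving_average_3(x)
        return build_regressors_ma(s, x, cfg.P)
    dec = hsvd_decompose(x, cfg.M)
    return build_regressors_hsvd(dec.low, dec.high, x, cfg.P, mode=cfg.hsvd_lag_mode)


def _fit_forecast_arima(cfg: ExperimentConfig, P: int, q: int, train: RegressorSet, test: RegressorSet):
    fit = fit_linear_ma(train, ArimaSpec(P, cfg.D, q))
    return fit, forecast_one_step(fit, test)


def _model_label(smoothing: str, model: str, cfg: ExperimentConfig, q: int) -> str:
    pre = "MA" if smoothing == "ma3" else "HSVD"
    if model == "arima":
        return f"{pre}-ARIMA({cfg.P},{cfg.D},{q})"
    suffix = "PSO" if model == "ann-pso" else "RPROP"
    return f"{pre}-ANN-{suffix}({cfg.P},{q},1)"


def _validate_report(report: dict) -> None:
    for key in ("config", "version", "models", "pitman"):
        if key not in report:
            raise FitError(f"report schema violation: missing {key!r}")
    for name, row in report["models"].items():
        for key in ("rmse", "gcv", "mape_percent", "chosen_q", "acf_white"):
            if key not in row:
                raise FitError(f"report row {name!r} missing {key!r}")


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full experiment and write reports; returns the report dict."""
    out = Path(out_dir)
    (out / "runs").mkdir(parents=True, exist_ok=True)
    (out / "predictions").mkdir(parents=True, exist_ok=True)

    raw = _load_series(cfg)
    if cfg.scaling == "minmax":
        n_fit = int(np.floor(cfg.train_fraction * raw.n))
        x, params = scale_minmax(raw, fit_count=n_fit)
    else:
        x, params = raw, None
    if cfg.D > 0:
        from .arima import difference

        x = TimeSeries(difference(x, cfg.D))

    results = {}
    errors_by_model = {}
    for smoothing in cfg.smoothings:
        rs = _build_regressors(cfg, smoothing, x)
        train, test = split_train_test(rs, cfg.train_fraction)
        for model in cfg.models:
            trace_rows = None
            best_trace = None
            if model == "arima":
                if cfg.q_scan is not None:
                    lo, hi = cfg.q_scan
                    q, scan_table = gcv_scan(
                        train,
                        lambda qq, tr, ho: _fit_forecast_arima(cfg, cfg.P, qq, tr, ho)[1],
                        range(lo, hi + 1),
                    )
                else:
                    q, scan_table = _int_keys(cfg.arima_q, "arima_q", smoothing), None
                fit, preds = _fit_forecast_arima(cfg, cfg.P, q, train, test)
            else:
                q = _int_keys(cfg.hidden, "hidden", smoothing)
                scan_table = None
                best_rmse, best_weights, best_trace, finals = np.inf, None, None, []
                for run in range(cfg.runs):
                    seed = cfg.seed_base + run
                    if model == "ann-pso":
                        w, trace = train_pso(train, rs.K, q, PsoConfig(**{**cfg.pso, "seed": seed}))
                    else:
                        w, trace = train_rprop(train, rs.K, q, RpropConfig(**{**cfg.rprop, "seed": seed}))
                    final = float(np.min(trace))
                    finals.append(final)
                    if final < best_rmse:
                        best_rmse, best_weights, best_trace = final, w, trace
                trace_rows = finals
                preds = ann_forward_batch(best_weights, test.rows)

            observed, predicted = test.targets, preds
            if cfg.original_scale and params is not None:
                observed = params.inverse(observed)
                predicted = params.inverse(predicted)
            fr = ForecastResult(observed, predicted, K=rs.K)
            metrics = forecast_metrics(fr)
            acf = acf_with_bounds(fr.errors, max_lag=min(20, fr.nv - 1))
            label = _model_label(smoothing, model, cfg, q)
            errors_by_model[label] = fr.errors
            results[label] = {
                "smoothing": smoothing,
                "model": model,
                "chosen_q": int(q),
                "rmse": metrics.rmse,
                "gcv": metrics.gcv,
                "mape_percent": metrics.mape_percent,
                "re_sum": metrics.re_sum,
                "nv": fr.nv,
                "K": rs.K,
                "acf_white": acf.white,
                "acf_conf_limit": acf.conf_limit,
            }
            if scan_table is not None:
                results[label]["gcv_scan"] = {str(k): v for k, v in scan_table.items()}
            pd.DataFrame(
                {
                    "period": test.t_index,
                    "observed": observed,
                    "predicted": predicted,
                    "error": observed - predicted,
                }
            ).to_csv(out / "predictions" / f"{label}.csv", index=False)
            if trace_rows is not None:
                pd.DataFrame({"run": range(len(trace_rows)), "final_fitness": trace_rows}).to_csv(
                    out / "runs" / f"{label}.csv", index=False
                )
                pd.DataFrame(
                    {"iteration": range(len(best_trace)), "fitness": best_trace}
                ).to_csv(out / "runs" / f"{label}_best_trace.csv", index=False)

    labels = list(results)
    pitman = {}
    matrix = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                continue
            cmp_ = pitman_test(errors_by_model[a], errors_by_model[b])
            matrix.loc[a, b] = cmp_.corr
            if i < j:
                pitman[f"{a} vs {b}"] = {
                    "corr": cmp_.corr,
                    "threshold": cmp_.threshold,
                    "significant": cmp_.significant,
                    "winner": {1: a, 2: b}.get(cmp_.winner),
                    "degenerate": cmp_.degenerate,
                }

    report = {
        "config": _config_echo(cfg),
        "version": __version__,
        "models": results,
        "pitman": pitman,
    }
    _validate_report(report)

    pd.DataFrame(
        [
            {"model": k, "rmse": v["rmse"], "gcv": v["gcv"], "mape": v["mape_percent"],
             "re_sum": v["re_sum"], "acf_white": v["acf_white"]}
            for k, v in results.items()
        ]
    ).to_csv(out / "metrics.csv", index=False)
    # upper-triangular layout: blank below the diagonal
    tri = matrix.copy().astype(object)
    for i, a in enumerate(labels):
        for j in range(i + 1):
            tri.iloc[i, j] = ""
    tri.to_csv(out / "pitman.csv")
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report


def _config_echo(cfg: ExperimentConfig) -> dict:
    echo = {}
    for name in cfg.__dataclass_fields__:
        value = getattr(cfg, name)
        if isinstance(value, tuple):
            value = list(value)
        echo[name] = value
    return echo
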