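# smoothcast

Two-stage forecasting for univariate, regularly sampled time series (e.g.
weekly surveillance counts):

1. **Smoothing** — either a centred 3-point moving average, or a Hankel-SVD
   decomposition (embed the series into a Hankel trajectory matrix, take the
   SVD, and reassemble one additive component per singular value from each
   rank-one term's first row and last column; component 1 is the
   low-frequency part `C_L`, the rest sum to the high-frequency part `C_H`,
   and `C_L + C_H` reconstructs the series exactly).
2. **Forecasting** — one-step-ahead, with teacher forcing, using either a
   linear model on the lagged smoothed regressors with moving-average error
   terms (fitted by conditional sum of squares), or a single-hidden-layer
   sigmoid network ANN(K, Q, 1) without biases, trained by particle swarm
   optimisation (linearly decreasing inertia) or by resilient
   backpropagation (iRPROP-).

Evaluation covers RMSE, GCV (`RMSE / (1 - K/Nv)^2`), MAPE, per-point
relative errors, residual-ACF whiteness at the 95% bands, and Pitman's
pairwise test of equal forecast-error variance (`corr(e1+e2, e1-e2)` against
`1.96/sqrt(Nv)`). A seeded synthetic-series generator (trend + seasonal +
noise, and ARMA) stands in for real surveillance data.

## CLI

The `smoothcast` entry point offers `simulate`, `smooth`, `decompose`,
`fit`, `evaluate` and `experiment`. Exit codes: 0 success, 2 configuration
error, 3 data error.

```sh
# generate a 531-point synthetic weekly series
smoothcast simulate --seed 42 --out series.csv

# decompose into low/high-frequency components (M = 2)
smoothcast decompose --in series.csv --out components.csv --m 2

# fit one model and write test predictions + metrics
smoothcast fit --in series.csv --model arima --smoothing hsvd \
    --p 9 --q 11 --out predictions.csv

# run the full smoothing x forecaster grid from a config file
smoothcast experiment --config experiment.json --out-dir results/
```

An experiment config (JSON or YAML) looks like:

```json
{
  "synthetic": {"n": 531, "base": 50, "seas_period": 52},
  "smoothings": ["ma3", "hsvd"],
  "models": ["arima", "ann-pso", "ann-rprop"],
  "P": 9, "D": 0, "M": 2,
  "arima_q": {"ma3": 10, "hsvd": 11},
  "hidden": {"ma3": 10, "hsvd": 11},
  "runs": 30,
  "seed_base": 42,
  "train_fraction": 0.85,
  "pso": {"itermax": 250}
}
```

The output directory contains `metrics.csv`, `pitman.csv` (upper-triangular
correlation matrix), `report.json`, per-model `predictions/*.csv` and, for
the stochastic trainers, `runs/*.csv` fitness traces. Stochastic models run
`runs` seeded repetitions (`seed_base + run_index`) and keep the best
training-fitness run; everything is reproducible from the config and seed.

Optional GCV-driven selection of the linear model's MA order: set
`"q_scan": [1, 18]` to scan Q on an inner chronological holdout (last 15%
of the training rows), with ties broken toward smaller Q.

## Package layout

| module                  | contents                                               |
|-------------------------|--------------------------------------------------------|
| `smoothcast.series`     | `TimeSeries` container, CSV I/O                        |
| `smoothcast.smoothing`  | 3-point MA, Hankel embedding, HSVD decomposition       |
| `smoothcast.lagspace`   | min-max scaling, lagged regressors, chronological split|
| `smoothcast.arima`      | differencing, CSS fit, teacher-forced forecasting      |
| `smoothcast.ann`        | forward pass, gradients, PSO and RPROP trainers        |
| `smoothcast.evaluation` | metrics, residual ACF, Pitman's test                   |
| `smoothcast.synthetic`  | seeded trend+seasonal and ARMA generators              |
| `smoothcast.pipeline`   | GCV scan, experiment orchestration                     |
| `smoothcast.cli`        | click command-line interface                           |
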