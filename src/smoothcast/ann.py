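"""Single-hidden-layer autoregressive network ANN(K, Q, 1).

Hidden units apply the logistic sigmoid to a weighted sum of the K lagged
inputs; the output is a linear combination of the Q hidden activations.
There are no bias terms, so the parameter count is D = K*Q + Q. Two batch
trainers are provided: particle swarm optimisation (linearly decreasing
inertia, attraction to personal and global bests) and resilient
backpropagation (sign-based per-weight step adaptation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import DimensionError, FitError
from .lagspace import RegressorSet

__all__ = [
    "AnnWeights",
    "PsoConfig",
    "RpropConfig",
    "ann_forward",
    "ann_forward_batch",
    "ann_gradients",
    "inertia_weight",
    "train_pso",
    "train_rprop",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


@dataclass(frozen=True)
class AnnWeights:
    """Hidden weights w (Q x K) and output weights v (Q)."""

    w: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if w.ndim != 2 or v.ndim != 1 or w.shape[0] != v.size:
            raise DimensionError(f"inconsistent weight shapes {w.shape}, {v.shape}")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "v", v)

    @property
    def K(self) -> int:
        return int(self.w.shape[1])

    @property
    def Q(self) -> int:
        return int(self.w.shape[0])

    @property
    def n_params(self) -> int:
        return self.K * self.Q + self.Q

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.w.ravel(), self.v])

    @staticmethod
    def from_vector(vec: np.ndarray, K: int, Q: int) -> "AnnWeights":
        vec = np.asarray(vec, dtype=float)
        if vec.size != K * Q + Q:
            raise DimensionError(f"expected {K * Q + Q} parameters, got {vec.size}")
        return AnnWeights(vec[: K * Q].reshape(Q, K), vec[K * Q:])


@dataclass(frozen=True)
class PsoConfig:
    np_particles: int = 30
    c1: float = 2.0
    c2: float = 2.0
    inertia_max: float = 0.9
    inertia_min: float = 0.4
    itermax: int = 2500
    init_range: float = 1.0
    velocity_range: float = 0.5
    pos_bound: float = 10.0  # reflective wall for particle positions
    seed: int = 0

    def __post_init__(self):
        if self.np_particles < 2:
            raise ValueError("swarm needs at least 2 particles")
        if not self.inertia_max > self.inertia_min > 0:
            raise ValueError("need inertia_max > inertia_min > 0")
        if self.itermax < 1:
            raise ValueError("need itermax >= 1")


@dataclass(frozen=True)
class RpropConfig:
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_min: float = 1e-6
    delta_max: float = 50.0
    epochs: int = 100
    init_range: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.eta_minus < 1 < self.eta_plus:
            raise ValueError("need 0 < eta_minus < 1 < eta_plus")
        if not 0 < self.delta_min <= self.delta0 <= self.delta_max:
            raise ValueError("step-size bounds must be ordered")


def ann_forward(weights: AnnWeights, z: np.ndarray) -> float:
    """Network output for one lag vector: sum_j v_j * sigmoid(w_j . z)."""
    z = np.asarray(z, dtype=float)
    if z.shape != (weights.K,):
        raise DimensionError(f"expected lag vector of length {weights.K}, got {z.shape}")
    h = _sigmoid(weights.w @ z)
    return float(weights.v @ h)


def ann_forward_batch(weights: AnnWeights, Z: np.ndarray) -> np.ndarray:
    """Vectorised forward pass over the rows of Z (n_rows x K)."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != weights.K:
        raise DimensionError(f"expected width {weights.K}, got {Z.shape[1]}")
    H = _sigmoid(Z @ weights.w.T)  # (n, Q)
    return H @ weights.v


def ann_gradients(weights: AnnWeights, batch: RegressorSet):
    """Exact gradient of E = sum_t (x_t - x_hat_t)^2 w.r.t. (w, v).

    Returns ``(grad_w, grad_v)`` with the shapes of ``w`` and ``v``.
    """
    Z = np.asarray(batch.rows, dtype=float)
    y = np.asarray(batch.targets, dtype=float)
    if Z.shape[0] == 0:
        raise FitError("empty batch")
    H = _sigmoid(Z @ weights.w.T)
    e = y - H @ weights.v
    grad_v = -2.0 * (H.T @ e)
    # dE/dw_ji = -2 sum_t e_t v_j h_j(1-h_j) z_i
    delta = (e[:, None] * H * (1.0 - H)) * weights.v[None, :]  # (n, Q)
    grad_w = -2.0 * (delta.T @ Z)
    return grad_w, grad_v


def inertia_weight(l: int, cfg: PsoConfig) -> float:
    """Linearly decreasing inertia: Imax at l=0 down to Imin at l=itermax."""
    return cfg.inertia_max - (cfg.inertia_max - cfg.inertia_min) * l / cfg.itermax


def _rmse(weights: AnnWeights, Z: np.ndarray, y: np.ndarray) -> float:
    e = y - ann_forward_batch(weights, Z)
    return float(np.sqrt(np.mean(e**2)))


def train_pso(train: RegressorSet, K: int, Q: int, cfg: PsoConfig):
    """PSO over the D = K*Q + Q weight dimensions; fitness is training RMSE.

    Velocity update: V <- I*V + c1*rd1*(p_best - X) + c2*rd2*(g_best - X),
    with rd uniform in [0, 1] per particle and dimension. Positions beyond
    ``pos_bound`` are reflected with the velocity component negated.
    Fully reproducible given the seed. Returns ``(best_weights, trace)``
    where ``trace[l]`` is the global-best RMSE after iteration l.
    """
    Z = np.asarray(train.rows, dtype=float)
    y = np.asarray(train.targets, dtype=float)
    if Z.shape[0] == 0:
        raise FitError("empty training set")
    if Z.shape[1] != K:
        raise DimensionError(f"training width {Z.shape[1]} != K={K}")
    rng = np.random.default_rng(cfg.seed)
    D = K * Q + Q
    X = rng.uniform(-cfg.init_range, cfg.init_range, size=(cfg.np_particles, D))
    V = rng.uniform(-cfg.velocity_range, cfg.velocity_range, size=(cfg.np_particles, D))

    def fitness(pos: np.ndarray) -> float:
        return _rmse(AnnWeights.from_vector(pos, K, Q), Z, y)

    fit = np.array([fitness(x) for x in X])
    pbest, pbest_fit = X.copy(), fit.copy()
    g = int(np.argmin(fit))
    gbest, gbest_fit = X[g].copy(), float(fit[g])

    trace = np.empty(cfg.itermax)
    for l in range(cfg.itermax):
        inertia = inertia_weight(l, cfg)
        rd1 = rng.uniform(size=(cfg.np_particles, D))
        rd2 = rng.uniform(size=(cfg.np_particles, D))
        V = inertia * V + cfg.c1 * rd1 * (pbest - X) + cfg.c2 * rd2 * (gbest[None, :] - X)
        X = X + V
        # reflect at the walls
        over = X > cfg.pos_bound
        under = X < -cfg.pos_bound
        X[over] = 2.0 * cfg.pos_bound - X[over]
        X[under] = -2.0 * cfg.pos_bound - X[under]
        V[over | under] *= -1.0
        fit = np.array([fitness(x) for x in X])
        if not np.all(np.isfinite(fit)):
            raise FitError(f"divergent fitness at iteration {l}")
        improved = fit < pbest_fit
        pbest[improved] = X[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        trace[l] = gbest_fit
    return AnnWeights.from_vector(gbest, K, Q), trace


def train_rprop(train: RegressorSet, K: int, Q: int, cfg: RpropConfig):
    """Batch RPROP (iRPROP-) on the sum-of-squared-error surface.

    Per-weight steps grow by ``eta_plus`` on a repeated gradient sign,
    shrink by ``eta_minus`` on a sign change (with the stored gradient
    zeroed so the next step adapts from scratch), and stay within
    ``[delta_min, delta_max]``. Returns ``(weights, trace)`` with the
    training RMSE after each epoch.
    """
    Z = np.asarray(train.rows, dtype=float)
    y = np.asarray(train.targets, dtype=float)
    if Z.shape[0] == 0:
        raise FitError("empty training set")
    if Z.shape[1] != K:
        raise DimensionError(f"training width {Z.shape[1]} != K={K}")
    rng = np.random.default_rng(cfg.seed)
    D = K * Q + Q
    theta = rng.uniform(-cfg.init_range, cfg.init_range, size=D)
    delta = np.full(D, cfg.delta0)
    prev_grad = np.zeros(D)

    trace = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        weights = AnnWeights.from_vector(theta, K, Q)
        gw, gv = ann_gradients(weights, train)
        grad = np.concatenate([gw.ravel(), gv])
        if not np.all(np.isfinite(grad)):
            raise FitError(f"non-finite gradient at epoch {epoch}")
        sign_prod = prev_grad * grad
        delta = np.where(sign_prod > 0, delta * cfg.eta_plus, delta)
        delta = np.where(sign_prod < 0, delta * cfg.eta_minus, delta)
        delta = np.clip(delta, cfg.delta_min, cfg.delta_max)
        grad = np.where(sign_prod < 0, 0.0, grad)  # no adaptation next step
        theta = theta - np.sign(grad) * delta
        prev_grad = grad
        trace[epoch] = _rmse(AnnWeights.from_vector(theta, K, Q), Z, y)
    return AnnWeights.from_vector(theta, K, Q), trace
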