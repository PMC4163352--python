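import numpy as np
import pytest

from smoothcast.ann import (
    AnnWeights,
    PsoConfig,
    RpropConfig,
    ann_forward,
    ann_forward_batch,
    ann_gradients,
    inertia_weight,
    train_pso,
    train_rprop,
)
from smoothcast.errors import DimensionError, FitError
from tests.conftest import make_regressors


def random_net(rng, K, Q, scale=1.0):
    return AnnWeights(rng.normal(scale=scale, size=(Q, K)), rng.normal(scale=scale, size=Q))


class TestForward:
    def test_zero_weights(self):
        w = AnnWeights(np.zeros((3, 2)), np.zeros(3))
        assert ann_forward(w, np.array([1.0, -4.0])) == 0.0

    def test_closed_form_sigmoid(self):
        # w = ln 3 -> h = 1/(1+1/3) = 0.75; v = 2 -> output 1.5
        w = AnnWeights(np.array([[np.log(3.0)]]), np.array([2.0]))
        assert ann_forward(w, np.array([1.0])) == pytest.approx(1.5, abs=1e-12)

    def test_linear_in_v(self, rng):
        w = rng.normal(size=(4, 3))
        z = rng.normal(size=3)
        v1, v2 = rng.normal(size=4), rng.normal(size=4)
        out = ann_forward(AnnWeights(w, v1 + 2 * v2), z)
        expected = ann_forward(AnnWeights(w, v1), z) + 2 * ann_forward(AnnWeights(w, v2), z)
        assert out == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch(self):
        w = AnnWeights(np.zeros((2, 3)), np.zeros(2))
        with pytest.raises(DimensionError):
            ann_forward(w, np.zeros(4))

    def test_param_count_no_bias(self):
        w = AnnWeights(np.zeros((10, 9)), np.zeros(10))
        assert w.n_params == 9 * 10 + 10

    def test_vector_round_trip(self, rng):
        w = random_net(rng, 3, 5)
        back = AnnWeights.from_vector(w.to_vector(), 3, 5)
        np.testing.assert_array_equal(back.w, w.w)
        np.testing.assert_array_equal(back.v, w.v)


class TestGradients:
    def test_zero_residuals_zero_gradient(self, rng):
        w = random_net(rng, 2, 3)
        Z = rng.normal(size=(20, 2))
        y = ann_forward_batch(w, Z)  # targets == outputs
        gw, gv = ann_gradients(w, make_regressors(Z, y))
        assert np.max(np.abs(gw)) < 1e-12 and np.max(np.abs(gv)) < 1e-12

    def test_finite_difference_oracle(self, rng):
        for _ in range(10):
            K, Q = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            Z = rng.normal(size=(12, K))
            y = rng.normal(size=12)
            rs = make_regressors(Z, y)
            w = random_net(rng, K, Q)
            gw, gv = ann_gradients(w, rs)
            g = np.concatenate([gw.ravel(), gv])
            vec = w.to_vector()
            h = 1e-6

            def energy(v):
                e = y - ann_forward_batch(AnnWeights.from_vector(v, K, Q), Z)
                return float(e @ e)

            for i in rng.choice(vec.size, size=min(6, vec.size), replace=False):
                step = np.zeros_like(vec)
                step[i] = h
                fd = (energy(vec + step) - energy(vec - step)) / (2 * h)
                assert abs(fd - g[i]) / (abs(fd) + 1e-8) < 1e-5

    def test_output_weight_gradient_formula(self, rng):
        w = random_net(rng, 2, 3)
        Z = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        _, gv = ann_gradients(w, make_regressors(Z, y))
        H = 1.0 / (1.0 + np.exp(-(Z @ w.w.T)))
        e = y - H @ w.v
        np.testing.assert_allclose(gv, -2.0 * H.T @ e, atol=1e-10)

    def test_empty_batch(self, rng):
        w = random_net(rng, 2, 2)
        rs = make_regressors(np.empty((0, 2)), np.empty(0))
        with pytest.raises(FitError):
            ann_gradients(w, rs)


class TestInertia:
    def test_bounds(self):
        cfg = PsoConfig(itermax=100)
        assert inertia_weight(0, cfg) == cfg.inertia_max
        assert inertia_weight(100, cfg) == pytest.approx(cfg.inertia_min)

    def test_midpoint(self):
        cfg = PsoConfig(itermax=100, inertia_max=0.9, inertia_min=0.4)
        assert inertia_weight(50, cfg) == pytest.approx(0.65)


class TestPso:
    def test_single_iteration_hand_unrolled(self, linear_regressors):
        cfg = PsoConfig(np_particles=2, itermax=1, seed=99)
        K, Q = 2, 2
        weights, trace = train_pso(linear_regressors, K, Q, cfg)
        # independent unroll of the same seeded recursion
        rng = np.random.default_rng(99)
        D = K * Q + Q
        X = rng.uniform(-cfg.init_range, cfg.init_range, size=(2, D))
        V = rng.uniform(-cfg.velocity_range, cfg.velocity_range, size=(2, D))
        Z, y = linear_regressors.rows, linear_regressors.targets

        def fitness(vec):
            e = y - ann_forward_batch(AnnWeights.from_vector(vec, K, Q), Z)
            return float(np.sqrt(np.mean(e**2)))

        fit = np.array([fitness(x) for x in X])
        pbest, pbest_fit = X.copy(), fit.copy()
        g = int(np.argmin(fit))
        gbest, gbest_fit = X[g].copy(), fit[g]
        rd1 = rng.uniform(size=(2, D))
        rd2 = rng.uniform(size=(2, D))
        V = cfg.inertia_max * V + cfg.c1 * rd1 * (pbest - X) + cfg.c2 * rd2 * (gbest - X)
        X = X + V
        fit = np.array([fitness(x) for x in X])
        for i in range(2):
            if fit[i] < pbest_fit[i]:
                pbest[i], pbest_fit[i] = X[i], fit[i]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), pbest_fit[g]
        np.testing.assert_allclose(weights.to_vector(), gbest)
        assert trace[-1] == pytest.approx(gbest_fit)

    def test_trace_monotone(self, linear_regressors):
        _, trace = train_pso(linear_regressors, 2, 3, PsoConfig(itermax=60, seed=5))
        assert np.all(np.diff(trace) <= 0)

    def test_convergence_linear_target(self, linear_regressors):
        _, trace = train_pso(linear_regressors, 2, 4, PsoConfig(itermax=500, seed=11))
        assert trace[-1] < 0.05

    def test_seeded_determinism(self, linear_regressors):
        w1, t1 = train_pso(linear_regressors, 2, 3, PsoConfig(itermax=30, seed=7))
        w2, t2 = train_pso(linear_regressors, 2, 3, PsoConfig(itermax=30, seed=7))
        np.testing.assert_array_equal(w1.to_vector(), w2.to_vector())
        np.testing.assert_array_equal(t1, t2)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            PsoConfig(np_particles=1)
        with pytest.raises(ValueError):
            PsoConfig(inertia_max=0.3, inertia_min=0.4)


class TestRprop:
    def test_zero_gradient_no_change(self):
        # targets exactly reproduced by the initial weights -> no movement
        rng = np.random.default_rng(0)
        cfg = RpropConfig(epochs=5, seed=4)
        # build weights from the same seed the trainer uses
        D = 2 * 3 + 3
        theta0 = np.random.default_rng(4).uniform(-cfg.init_range, cfg.init_range, size=D)
        w0 = AnnWeights.from_vector(theta0, 2, 3)
        Z = rng.normal(size=(20, 2))
        y = ann_forward_batch(w0, Z)
        w, _ = train_rprop(make_regressors(Z, y), 2, 3, cfg)
        np.testing.assert_allclose(w.to_vector(), theta0, atol=1e-12)

    def test_scalar_quadratic_rule_oracle(self):
        # independent scalar simulation of the adaptation rule on E=(w-3)^2
        w, delta, prev = 0.0, 0.1, 0.0
        for _ in range(60):
            grad = 2.0 * (w - 3.0)
            if prev * grad > 0:
                delta = min(delta * 1.2, 50.0)
            elif prev * grad < 0:
                delta = max(delta * 0.5, 1e-6)
                grad = 0.0
            w -= np.sign(grad) * delta
            prev = grad
        assert abs(w - 3.0) < 1e-3

    def test_step_growth_on_constant_sign(self, rng):
        # large positive targets keep dE/dv negative for several epochs:
        # consecutive steps on v grow by exactly eta_plus
        Z = rng.uniform(0.5, 1.0, size=(30, 2))
        y = np.full(30, 50.0)
        rs = make_regressors(Z, y)
        cfg = RpropConfig(delta0=0.1, seed=2)
        thetas = []
        for epochs in (1, 2, 3):
            w, _ = train_rprop(rs, 2, 1, RpropConfig(delta0=0.1, seed=2, epochs=epochs))
            thetas.append(w.to_vector())
        step1 = thetas[1] - thetas[0]
        step2 = thetas[2] - thetas[1]
        v_idx = 2  # output weight, K*Q = 2 hidden weights first
        assert step1[v_idx] == pytest.approx(0.1 * cfg.eta_plus)
        assert step2[v_idx] == pytest.approx(0.1 * cfg.eta_plus**2)

    def test_convergence_linear_target(self, linear_regressors):
        _, trace = train_rprop(linear_regressors, 2, 4, RpropConfig(epochs=100, seed=11))
        assert trace.min() < 0.05

    def test_seeded_determinism(self, linear_regressors):
        w1, t1 = train_rprop(linear_regressors, 2, 3, RpropConfig(epochs=20, seed=9))
        w2, t2 = train_rprop(linear_regressors, 2, 3, RpropConfig(epochs=20, seed=9))
        np.testing.assert_array_equal(w1.to_vector(), w2.to_vector())
        np.testing.assert_array_equal(t1, t2)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            RpropConfig(eta_minus=1.5)
        with pytest.raises(ValueError):
            RpropConfig(delta0=100.0, delta_max=50.0)
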