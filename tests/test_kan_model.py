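"""KAN forward pass, loss, training and pruning."""

import numpy as np
import pytest

from sprintkan import kan


def least_squares_edge(grid, xs, ys):
    """Oracle: direct least-squares spline fit of one edge."""
    B = kan.basis_matrix(xs, grid)
    coef, *_ = np.linalg.lstsq(B, ys, rcond=None)
    return coef


class TestForward:
    def test_zero_coefficients_give_zero(self):
        m = kan.KANModel.init((9, 5, 3, 1), 5, seed=0)
        for l in range(m.n_layers):
            m.coeffs[l][:] = 0.0
        m.fit_scaler(np.random.default_rng(0).uniform(0, 1, (10, 9)))
        X = np.random.default_rng(1).uniform(0, 1, (20, 9))
        np.testing.assert_allclose(m.forward(X), 0.0)

    def test_single_edge_identity_fit(self):
        """A 1->1 edge least-squares fit to g(x)=x reproduces it to 1e-3."""
        grid = kan.SplineGrid(5)
        xs = np.linspace(0, 1, 50)
        coef = least_squares_edge(grid, xs, xs)
        m = kan.KANModel.init((1, 1), 5, seed=0)
        m.coeffs[0][0, 0, :] = coef
        m.scaler_min, m.scaler_max = np.zeros(1), np.ones(1)
        xq = np.linspace(0.05, 0.95, 200)
        assert np.max(np.abs(m.forward(xq[:, None]) - xq)) < 1e-3

    def test_last_layer_linearity(self):
        m = kan.KANModel.init((3, 2, 1), 4, seed=2)
        X = np.random.default_rng(3).uniform(0, 1, (15, 3))
        m.fit_scaler(X)
        y1 = m.forward(X)
        m.coeffs[-1] *= 2.0
        np.testing.assert_allclose(m.forward(X), 2 * y1, atol=1e-12)

    def test_unfitted_scaler_rejected(self):
        m = kan.KANModel.init((2, 1), 5, seed=0)
        with pytest.raises(ValueError):
            m.forward(np.zeros((3, 2)))

    def test_kan_forward_single_row(self):
        m = kan.KANModel.init((2, 1), 5, seed=0)
        m.fit_scaler(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert isinstance(kan.kan_forward(m, np.array([0.5, 0.5])), float)

    def test_json_roundtrip(self):
        m = kan.KANModel.init((3, 2, 1), 4, seed=5)
        X = np.random.default_rng(0).uniform(0, 1, (10, 3))
        m.fit_scaler(X)
        m2 = kan.KANModel.from_json(m.to_json())
        np.testing.assert_allclose(m.forward(X), m2.forward(X))


class TestLoss:
    def test_edge_entropy_degenerate_and_uniform(self):
        assert kan.edge_entropy([0.0, 0.0, 3.0, 0.0]) == 0.0
        assert kan.edge_entropy([1.0, -1.0, 1.0, -1.0]) == pytest.approx(
            np.log(4), abs=1e-9)

    def test_zero_model_mse_is_variance(self):
        m = kan.KANModel.init((2, 1), 5, seed=0)
        for l in range(m.n_layers):
            m.coeffs[l][:] = 0.0
        X = np.random.default_rng(0).uniform(0, 1, (50, 2))
        y = np.random.default_rng(1).normal(size=50)
        y = y - y.mean()  # centred targets
        m.fit_scaler(X)
        lb = kan.loss(m, X, y)
        assert lb.mse == pytest.approx(np.var(y))
        assert lb.l1_term == 0.0 and lb.entropy_term == 0.0

    def test_total_composition(self):
        cfg = kan.TrainConfig(lam=0.01, mu1=1.0, mu2=10.0)
        m = kan.KANModel.init((2, 2, 1), 4, seed=1)
        X = np.random.default_rng(2).uniform(0, 1, (30, 2))
        y = np.random.default_rng(3).normal(size=30)
        m.fit_scaler(X)
        lb = kan.loss(m, X, y, cfg)
        assert lb.total == pytest.approx(
            lb.mse + cfg.lam * (cfg.mu1 * lb.l1_term + cfg.mu2 * lb.entropy_term))
        assert np.isfinite([lb.mse, lb.l1_term, lb.entropy_term, lb.total]).all()


class TestTrain:
    def test_noiseless_linear_target(self):
        """1->1 network on y = 2 x: representable exactly, trained MSE
        below 1e-4."""
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (100, 1))
        y = 2 * X[:, 0]
        cfg = kan.TrainConfig(lam=0.0, widths=(1, 1))
        m, _ = kan.train(kan.KANModel.init((1, 1), 5, seed=0), X, y, cfg)
        assert np.mean((m.forward(X) - y) ** 2) < 1e-4

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (50, 2))
        y = X[:, 0] - X[:, 1]
        cfg = kan.TrainConfig(widths=(2, 1))
        m1, _ = kan.train(kan.KANModel.init((2, 1), 5, seed=3), X, y, cfg)
        m2, _ = kan.train(kan.KANModel.init((2, 1), 5, seed=3), X, y, cfg)
        for a, b in zip(m1.coeffs, m2.coeffs):
            np.testing.assert_array_equal(a, b)

    def test_regularization_tradeoff(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (80, 2))
        y = np.sin(3 * X[:, 0]) + 0.1 * rng.normal(size=80)
        mses = {}
        for lam in (0.0, 0.01):
            cfg = kan.TrainConfig(lam=lam, widths=(2, 1))
            m, _ = kan.train(kan.KANModel.init((2, 1), 5, seed=0), X, y, cfg)
            mses[lam] = np.mean((m.forward(X) - y) ** 2)
        assert mses[0.0] <= mses[0.01] + 1e-12

    def test_loss_history_non_increasing(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (60, 3))
        y = X @ np.array([1.0, -0.5, 0.2])
        cfg = kan.TrainConfig(widths=(3, 2, 1))
        _, hist = kan.train(kan.KANModel.init((3, 2, 1), 5, seed=0), X, y, cfg)
        assert all(b <= a + 1e-10 for a, b in zip(hist, hist[1:]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        m = kan.KANModel.init((3, 2, 1), 4, seed=1)
        X = rng.uniform(0, 1, (20, 3))
        y = rng.normal(size=20)
        m.fit_scaler(X)
        cfg = kan.TrainConfig(widths=(3, 2, 1), grid=4)
        theta = kan._get_flat(m)
        f0, g0 = kan._objective(theta.copy(), m.copy(), X, y, cfg)
        idx = np.arange(0, theta.size, 5)
        eps = 1e-6
        num = []
        for i in idx:
            tp = theta.copy()
            tp[i] += eps
            num.append((kan._objective(tp, m.copy(), X, y, cfg)[0] - f0) / eps)
        np.testing.assert_allclose(np.array(num), g0[idx], atol=1e-4)


class TestRSquared:
    def test_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        assert kan.r_squared(y, y) == 1.0
        assert kan.r_squared(np.full(3, 2.0), y) == 0.0

    def test_residuals_twice_the_deviations(self):
        # residuals twice as large as y's own deviations about its mean
        y = np.array([0.0, 2.0])
        yhat = np.array([-2.0, 4.0])
        assert kan.r_squared(yhat, y) == pytest.approx(-3.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            kan.r_squared(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestPrune:
    def _trained_planted(self, seed):
        """x1 and x7 drive the outcome; remaining inputs are pure noise."""
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (240, 9))
        y = 2.0 * X[:, 0] + 1.5 * X[:, 6] + 0.05 * rng.normal(size=240)
        cfg = kan.TrainConfig(seed=seed)
        model, _ = kan.fit_kan(X, y, cfg)
        return model

    def test_zero_threshold_prunes_nothing(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (50, 3))
        y = X.sum(axis=1)
        cfg = kan.TrainConfig(widths=(3, 2, 1))
        m, _ = kan.train(kan.KANModel.init((3, 2, 1), 5, seed=0), X, y, cfg)
        pr = kan.prune(m, X, threshold=0.0)
        assert all(mask.all() for mask in pr.masks)

    def test_infinite_threshold_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (50, 3))
        y = X.sum(axis=1)
        cfg = kan.TrainConfig(widths=(3, 2, 1))
        m, _ = kan.train(kan.KANModel.init((3, 2, 1), 5, seed=0), X, y, cfg)
        with pytest.raises(ValueError):
            kan.prune(m, X, threshold=np.inf)

    def test_pruned_forward_equals_masked_forward(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (60, 4))
        y = X[:, 0] ** 2
        cfg = kan.TrainConfig(widths=(4, 2, 1))
        m, _ = kan.train(kan.KANModel.init((4, 2, 1), 5, seed=0), X, y, cfg)
        pr = kan.prune(m, X, 0.2)
        zeroed = m.copy()
        for l in range(m.n_layers):
            zeroed.coeffs[l][~pr.masks[l]] = 0.0
            zeroed.masks[l] = pr.masks[l]
        np.testing.assert_array_equal(pr.forward(X), zeroed.forward(X))

    def test_planted_input_recovery(self):
        """Over 10 seeds, the pruned input set contains the planted inputs
        {x1, x7} and at most 4 inputs survive in at least 8 cases."""
        good = 0
        for seed in range(10):
            model = self._trained_planted(seed)
            survivors = set(kan.surviving_inputs(model))
            good += ({0, 6} <= survivors) and (len(survivors) <= 4)
        assert good >= 8
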