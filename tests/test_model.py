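"""Model-fitting unit tests and oracle-equivalence checks."""

import numpy as np
import pytest
import scipy.optimize

from mlmr.exceptions import (
    InvalidInputError,
    InvalidParameterError,
    NoLabeledInstancesError,
)
from mlmr.graph import KernelConfig, SparsifierConfig, build_graph, gaussian_kernel
from mlmr.model import (
    HyperParams,
    LabelMask,
    ModelState,
    build_psi,
    build_reliance,
    fit,
    fit_pipeline,
    load_model,
    objective_value,
    predict_scores,
    save_model,
    threshold_labels,
    transductive_scores,
)


class TestPsiAndReliance:
    def test_labeled_first_layout(self):
        mask = build_psi(np.array([True, False, True, False]))
        assert mask.l == 2 and mask.u == 2
        assert np.array_equal(mask.psi, [1, 1, 0, 0])
        assert np.array_equal(mask.order, [0, 2, 1, 3])
        assert np.array_equal(mask.order[mask.inverse], np.arange(4))

    def test_all_labeled_gives_identity_mask(self):
        mask = build_psi(np.ones(3, dtype=bool))
        assert np.array_equal(mask.psi, np.ones(3))

    def test_no_labels_raises(self):
        with pytest.raises(NoLabeledInstancesError):
            build_psi(np.zeros(4, dtype=bool))

    def test_uniform_reliance_weights(self):
        mask = build_psi(np.array([True, True, False, False]))
        assert np.array_equal(build_reliance(mask, 1.0, 0.1), [1.0, 1.0, 0.1, 0.1])
        assert np.array_equal(build_reliance(mask, 1.0, 1.0), np.ones(4))

    def test_negative_weight_rejected(self):
        mask = build_psi(np.array([True, False]))
        with pytest.raises(InvalidParameterError):
            build_reliance(mask, 1.0, -0.5)
        with pytest.raises(InvalidParameterError):
            HyperParams(nu2=-0.5)


def _loop_objective(F, Y, l, n, L_lap, gA, gI, f_norm_sq):
    """Scalar-loop evaluation of the regularized risk (independent oracle)."""
    loss = 0.0
    for i in range(l):
        for j in range(F.shape[1]):
            loss += (F[i, j] - Y[i, j]) ** 2
    smooth = 0.0
    for a in range(n):
        for b in range(n):
            for j in range(F.shape[1]):
                smooth += F[a, j] * L_lap[a, b] * F[b, j]
    return loss / l + gA * f_norm_sq + gI / n**2 * smooth


class TestObjective:
    def test_zero_at_perfect_fit_without_regularization(self):
        mask = build_psi(np.ones(3, dtype=bool))
        Y = np.array([[1.0, -1.0]] * 3)
        hyper = HyperParams(gamma_A=1e-12, gamma_I=0.0)
        val = objective_value(Y, Y, mask, np.zeros((3, 3)), hyper, f_norm_sq=0.0)
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_constant_rows_kill_smoothness_term(self, rng):
        W = np.abs(rng.normal(size=(4, 4)))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        L_lap = np.diag(W.sum(1)) - W
        mask = build_psi(np.ones(4, dtype=bool))
        F = np.tile([2.0, -3.0], (4, 1))
        hyper = HyperParams(gamma_A=1e-9, gamma_I=5.0)
        val = objective_value(F, F, mask, L_lap, hyper, f_norm_sq=0.0)
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_matches_scalar_loop(self, rng):
        n, L_dim, l = 6, 2, 4
        mask = build_psi(np.arange(n) < l)
        W = np.abs(rng.normal(size=(n, n)))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        L_lap = np.diag(W.sum(1)) - W
        F = rng.normal(size=(n, L_dim))
        Y = np.zeros((n, L_dim))
        Y[:l] = rng.choice([-1.0, 1.0], size=(l, L_dim))
        hyper = HyperParams(gamma_A=0.3, gamma_I=0.7)
        got = objective_value(F, Y, mask, L_lap, hyper, f_norm_sq=1.23)
        want = _loop_objective(F, Y, l, n, L_lap, 0.3, 0.7, 1.23)
        assert got == pytest.approx(want, rel=1e-12)


def _minimize_objective(K, L_lap, Y, mask, hyper):
    """Generic numerical minimizer of the risk over Theta (Xi = I oracle)."""
    n, L_dim = Y.shape
    l = mask.l
    psi = mask.psi

    def obj_grad(t):
        Theta = t.reshape(n, L_dim)
        F = K @ Theta
        R = psi[:, None] * F - Y
        val = (
            np.trace(R.T @ R) / l
            + hyper.gamma_A * np.trace(Theta.T @ K @ Theta)
            + hyper.gamma_I / n**2 * np.trace(F.T @ L_lap @ F)
        )
        grad = (
            (2.0 / l) * K @ (psi[:, None] * R)
            + 2.0 * hyper.gamma_A * K @ Theta
            + (2.0 * hyper.gamma_I / n**2) * K @ L_lap @ (K @ Theta)
        )
        return val, grad.ravel()

    res = scipy.optimize.minimize(
        obj_grad,
        np.zeros(n * L_dim),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return res.fun


def _random_problem(rng, n, L_dim, l, gamma_I=0.1):
    X = rng.normal(size=(n, 3))
    K = gaussian_kernel(X, KernelConfig(sigma=1.5))
    g = build_graph(X, KernelConfig(sigma=1.5), SparsifierConfig(method="knn", k=3))
    mask = build_psi(np.arange(n) < l)
    Y = np.zeros((n, L_dim))
    Y[:l] = rng.choice([-1.0, 1.0], size=(l, L_dim))
    hyper = HyperParams(gamma_A=0.05, gamma_I=gamma_I, nu1=1.0, nu2=1.0)
    return X, K, g.L, Y, mask, hyper


class TestFit:
    def test_identity_kernel_closed_form(self):
        n, L_dim = 4, 2
        mask = build_psi(np.ones(n, dtype=bool))
        Y = np.array([[1.0, -1], [-1, 1], [1, 1], [-1, -1]])
        hyper = HyperParams(gamma_A=0.5, gamma_I=0.0)
        m = fit(np.eye(n), np.zeros((n, n)), Y, mask, np.ones(n), hyper)
        assert np.allclose(m.theta, Y / (1 + n * 0.5))

    def test_closed_form_attains_numerical_optimum(self, rng):
        """The linear-solve solution is at least as good as L-BFGS on the risk."""
        X, K, L_lap, Y, mask, hyper = _random_problem(rng, n=20, L_dim=3, l=8)
        m = fit(K, L_lap, Y, mask, np.ones(mask.n), hyper)
        f_norm = float(np.trace(m.theta.T @ K @ m.theta))
        closed = objective_value(K @ m.theta, Y, mask, L_lap, hyper, f_norm)
        numeric = _minimize_objective(K, L_lap, Y, mask, hyper)
        assert closed <= numeric * (1 + 1e-4)

    def test_reduction_to_unweighted_model(self, rng):
        """nu1 = nu2 = 1 reproduces the solve with the reliance diagonal omitted."""
        X, K, L_lap, Y, mask, hyper = _random_problem(rng, n=15, L_dim=2, l=6)
        m = fit(K, L_lap, Y, mask, build_reliance(mask, 1.0, 1.0), hyper)
        n, l = mask.n, mask.l
        A = mask.psi[:, None] * K + l * hyper.gamma_A * np.eye(n)
        A += (l * hyper.gamma_I / n**2) * (L_lap @ K)
        theta_plain = np.linalg.solve(A, Y)
        assert np.allclose(m.theta, theta_plain, atol=1e-8)

    def test_supervised_limit_ignores_unlabeled_coefficients(self, rng):
        """With nu2 = 0, perturbing unlabeled rows of Theta leaves scores unchanged."""
        X, K, L_lap, Y, mask, _ = _random_problem(rng, n=15, L_dim=2, l=5)
        hyper = HyperParams(gamma_A=0.05, gamma_I=0.1, nu1=1.0, nu2=0.0)
        xi = build_reliance(mask, 1.0, 0.0)
        m = fit(K, L_lap, Y, mask, xi, hyper, X_train=X, kernel_cfg=KernelConfig(sigma=1.5))
        X_test = rng.normal(size=(4, 3))
        before = predict_scores(m, X_test)
        m.theta[mask.l :] += rng.normal(size=m.theta[mask.l :].shape) * 100
        assert np.array_equal(before, predict_scores(m, X_test))

    def test_unlabeled_rows_must_be_zero(self, rng):
        X, K, L_lap, Y, mask, hyper = _random_problem(rng, n=10, L_dim=2, l=4)
        Y_bad = Y.copy()
        Y_bad[-1, 0] = 1.0
        with pytest.raises(InvalidInputError):
            fit(K, L_lap, Y_bad, mask, np.ones(mask.n), hyper)

    def test_predictions_continuous_in_nu2(self, rng):
        X, K, L_lap, Y, mask, _ = _random_problem(rng, n=15, L_dim=2, l=6)
        cfg = KernelConfig(sigma=1.5)
        X_test = rng.normal(size=(3, 3))
        scores = []
        for nu2 in (0.1, 0.1 + 1e-6):
            hyper = HyperParams(gamma_A=0.05, gamma_I=0.1, nu1=1.0, nu2=nu2)
            m = fit(K, L_lap, Y, mask, build_reliance(mask, 1.0, nu2), hyper,
                    X_train=X, kernel_cfg=cfg)
            scores.append(predict_scores(m, X_test))
        assert np.max(np.abs(scores[1] - scores[0])) < 1e-3

    def test_weighted_kernel_quadratic_form_nonneg(self, rng):
        """For entrywise non-negative v and Xi >= 0, v^T K Xi v >= 0 when K >= 0."""
        for _ in range(20):
            K = gaussian_kernel(rng.normal(size=(8, 2)), KernelConfig())
            xi = rng.uniform(0, 1, size=8)
            v = rng.uniform(0, 1, size=8)
            assert v @ (K * xi[None, :]) @ v >= 0


class TestPredictAndThreshold:
    def test_basis_row_kernel_selects_coefficient_row(self):
        n, L_dim = 4, 3
        theta = np.arange(n * L_dim, dtype=float).reshape(n, L_dim)
        mask = build_psi(np.ones(n, dtype=bool))
        m = ModelState(theta=theta, xi=np.ones(n), X_train=None, kernel_cfg=None,
                       hyper=HyperParams(), mask=mask)
        K_e = np.zeros((1, n))
        K_e[0, 2] = 1.0
        scores = (K_e * m.xi[None, :]) @ m.theta
        assert np.array_equal(scores[0], theta[2])

    def test_zero_reliance_annihilates_scores(self, rng):
        X = rng.normal(size=(6, 3))
        mask = build_psi(np.ones(6, dtype=bool))
        m = ModelState(theta=rng.normal(size=(6, 2)), xi=np.zeros(6), X_train=X,
                       kernel_cfg=KernelConfig(), hyper=HyperParams(), mask=mask)
        assert np.all(predict_scores(m, X) == 0)

    def test_threshold_rule_and_antisymmetry(self):
        F = np.array([[0.2, -0.3, 0.0]])
        assert np.array_equal(threshold_labels(F), [[1, -1, -1]])
        assert np.array_equal(threshold_labels(np.full((2, 2), 0.5)), np.ones((2, 2)))
        G = np.array([[1.5, -2.0, 0.7]])
        assert np.array_equal(threshold_labels(-G), -threshold_labels(G))


class TestPipeline:
    def test_separable_clusters_reproduced_exactly(self, small_dataset):
        """Fully labeled, well-separated clusters: training labels recovered."""
        X, Y = small_dataset
        hyper = HyperParams(gamma_A=0.001, gamma_I=0.0, nu1=1.0, nu2=1.0)
        model, graph = fit_pipeline(X, Y.astype(float), KernelConfig(sigma=1.0),
                                    SparsifierConfig(method="knn", k=3), hyper)
        F = transductive_scores(model, graph.U)
        assert np.array_equal(threshold_labels(F), Y)

    def test_determinism(self, small_dataset):
        X, Y = small_dataset
        Yp = Y.astype(float).copy()
        Yp[10:20] = 0
        runs = [fit_pipeline(X, Yp, KernelConfig(sigma=1.0))[0].theta for _ in range(2)]
        assert np.array_equal(runs[0], runs[1])

    def test_unlabeled_everything_raises(self, small_dataset):
        X, Y = small_dataset
        with pytest.raises(NoLabeledInstancesError):
            fit_pipeline(X, np.zeros_like(Y, dtype=float))

    def test_model_roundtrip(self, small_dataset, tmp_path):
        X, Y = small_dataset
        Yp = Y.astype(float).copy()
        Yp[5:25] = 0
        model, _ = fit_pipeline(X, Yp, KernelConfig(sigma=1.0))
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        X_test = X[:4] + 0.05
        assert np.allclose(predict_scores(model, X_test), predict_scores(loaded, X_test))
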