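import numpy as np
import pytest

from t2mvpa.svr import EpsilonSVR, EpsilonSVRResults, SvrConfig, fit_svr


def slsqp_dual_optimum(X, y, C, eps):
    """Independent dense QP solve of the dual (generic solver, SLSQP)."""
    from scipy.optimize import LinearConstraint, minimize
    n = len(y)
    K = X @ X.T

    def negdual(z):
        beta = z[:n] - z[n:]
        return 0.5 * beta @ K @ beta - y @ beta + eps * z.sum()

    def grad(z):
        Kb = K @ (z[:n] - z[n:])
        return np.concatenate([Kb - y + eps, -Kb + y + eps])

    A = np.concatenate([np.ones(n), -np.ones(n)])[None, :]
    res = None
    for ftol in (1e-14, 1e-12, 1e-10):  # SLSQP line search can stall at
        res = minimize(negdual, np.zeros(2 * n), jac=grad, method="SLSQP",
                       bounds=[(0, C)] * (2 * n),
                       constraints=[LinearConstraint(A, 0, 0)],
                       options={"maxiter": 5000, "ftol": ftol})
        if res.success:
            break
    assert res.success, res.message
    return -res.fun


def random_instance(rng):
    n = int(rng.integers(4, 13))
    d = int(rng.integers(1, 7))
    X = rng.normal(size=(n, d))
    y = X @ rng.normal(size=d) + 0.3 * rng.normal(size=n)
    C = float(rng.uniform(0.5, 10.0))
    eps = float(rng.uniform(0.01, 0.5))
    return X, y, C, eps


class TestFit:
    def test_flat_solution_when_targets_within_tube(self):
        # all targets within eps of a constant -> w = 0 is optimal
        X = np.random.default_rng(0).normal(size=(3, 2))
        res = fit_svr(X, [0.9, 1.0, 1.1], SvrConfig(C=5.0, epsilon=0.2))
        assert np.allclose(res.params, 0.0, atol=1e-8)
        assert np.all(np.abs(res.predict(X) - [0.9, 1.0, 1.1]) <= 0.2 + 1e-8)

    def test_interpolates_exact_linear_data(self):
        x = np.linspace(-1, 1, 7)[:, None]
        res = fit_svr(x, 2.0 * x.ravel(), SvrConfig(C=1e3, epsilon=0.0))
        assert res.params[0] == pytest.approx(2.0, abs=1e-6)
        assert res.bias == pytest.approx(0.0, abs=1e-6)

    def test_dual_feasibility_invariants(self, rng):
        for _ in range(10):
            X, y, C, eps = random_instance(rng)
            res = fit_svr(X, y, SvrConfig(C=C, epsilon=eps, kkt_tol=1e-8))
            assert np.all(res.alpha >= 0) and np.all(res.alpha <= C + 1e-10)
            assert np.all(res.alpha_star >= 0) and np.all(res.alpha_star <= C + 1e-10)
            # alpha and alpha* never simultaneously nonzero
            assert np.all(res.alpha * res.alpha_star == 0)
            assert abs(res.beta.sum()) < 1e-8 * max(1.0, C)
            assert np.all(res.slack >= 0) and np.all(res.slack_star >= 0)

    def test_duality_gap_small(self, rng):
        for _ in range(10):
            X, y, C, eps = random_instance(rng)
            res = fit_svr(X, y, SvrConfig(C=C, epsilon=eps, kkt_tol=1e-8))
            scale = max(1.0, abs(res.primal_objective))
            assert res.duality_gap / scale < 1e-6

    def test_complementary_slackness(self, rng):
        tol = 1e-6
        for _ in range(10):
            X, y, C, eps = random_instance(rng)
            res = fit_svr(X, y, SvrConfig(C=C, epsilon=eps, kkt_tol=1e-8))
            resid = res.model.endog - res.predict(X)
            # alpha > 0 -> residual at or beyond +eps; alpha < C -> no slack
            active = res.alpha > 1e-8 * C
            assert np.all(resid[active] >= eps - tol * max(1, np.abs(y).max()))
            inactive = res.alpha < C * (1 - 1e-8)
            assert np.all(res.slack[inactive] <= tol * max(1, np.abs(y).max()))
            active_s = res.alpha_star > 1e-8 * C
            assert np.all(-resid[active_s] >= eps - tol * max(1, np.abs(y).max()))

    def test_translation_equivariance(self, rng):
        X, y, C, eps = random_instance(rng)
        cfg = SvrConfig(C=C, epsilon=eps, kkt_tol=1e-9)
        base = fit_svr(X, y, cfg)
        shifted = fit_svr(X, y + 100.0, cfg)
        assert np.allclose(shifted.params, base.params, atol=1e-5)
        assert shifted.bias == pytest.approx(base.bias + 100.0, abs=1e-5)

    def test_feature_permutation_equivariance(self, rng):
        X, y, C, eps = random_instance(rng)
        perm = rng.permutation(X.shape[1])
        cfg = SvrConfig(C=C, epsilon=eps, kkt_tol=1e-9)
        base = fit_svr(X, y, cfg)
        permed = fit_svr(X[:, perm], y, cfg)
        assert np.allclose(permed.params, base.params[perm], atol=1e-6)

    def test_auto_hyperparameters_resolve_from_targets(self):
        y = np.array([0.0, 10.0, 20.0, 30.0])
        C, eps = SvrConfig().resolve(y)
        sd = y.std()
        assert C == pytest.approx(max(abs(15 + 3 * sd), abs(15 - 3 * sd)))
        assert eps == pytest.approx(0.1 * sd)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_svr(np.ones((2, 2)) * np.nan, [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_svr(np.ones((1, 2)), [1.0])
        with pytest.raises(ValueError):
            SvrConfig(C=-1.0)
        with pytest.raises(ValueError):
            SvrConfig(epsilon=-0.1)

    def test_max_iter_exceeded_reports_violation(self, rng):
        from t2mvpa.svr import SvrConvergenceError
        X, y, C, eps = random_instance(rng)
        with pytest.raises(SvrConvergenceError) as err:
            fit_svr(X, y, SvrConfig(C=C, epsilon=eps, kkt_tol=1e-12, max_iter=1))
        assert err.value.violation > 0


class TestPredict:
    def test_zero_weights_predict_bias(self):
        X = np.random.default_rng(1).normal(size=(4, 3))
        res = fit_svr(X, [1.0, 1.05, 0.95, 1.0], SvrConfig(C=1.0, epsilon=0.2))
        assert np.allclose(res.predict(np.zeros((2, 3))), res.bias)

    def test_training_residuals_within_tube_when_feasible(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 2))
        y = X @ [1.0, -2.0] + 0.5
        res = fit_svr(X, y, SvrConfig(C=1e4, epsilon=0.05))
        assert np.all(np.abs(res.predict(X) - y) <= 0.05 + 1e-6)

    def test_dimension_mismatch(self):
        X = np.eye(3)
        res = fit_svr(X, [1.0, 2.0, 3.0], SvrConfig(C=10.0, epsilon=0.0))
        with pytest.raises(ValueError):
            res.predict(np.ones((1, 5)))


class TestOracleEquivalence:
    def test_matches_generic_qp_objective(self, rng):
        for _ in range(15):
            X, y, C, eps = random_instance(rng)
            ours = fit_svr(X, y, SvrConfig(C=C, epsilon=eps, kkt_tol=1e-9))
            ref = slsqp_dual_optimum(X, y, C, eps)
            assert ours.dual_objective == pytest.approx(
                ref, rel=1e-6, abs=1e-8)

    def test_matches_sklearn_predictions(self, rng):
        sk = pytest.importorskip("sklearn.svm")
        for _ in range(15):
            X, y, C, eps = random_instance(rng)
            ours = fit_svr(X, y, SvrConfig(C=C, epsilon=eps, kkt_tol=1e-9))
            ref = sk.SVR(kernel="linear", C=C, epsilon=eps, tol=1e-8).fit(X, y)
            scale = max(1.0, np.abs(y).max())
            assert np.abs(ours.predict(X) - ref.predict(X)).max() / scale < 1e-4


class TestSerialization:
    def test_json_roundtrip_predicts_identically(self, tmp_path, rng):
        X, y, C, eps = random_instance(rng)
        res = fit_svr(X, y, SvrConfig(C=C, epsilon=eps))
        path = tmp_path / "model.json"
        res.to_json(path)
        loaded = EpsilonSVRResults.predictor_from_json(path)
        assert np.allclose(loaded(X), res.predict(X), atol=1e-12)

    def test_summary_mentions_hyperparameters(self, rng):
        X, y, C, eps = random_instance(rng)
        res = fit_svr(X, y, SvrConfig(C=C, epsilon=eps))
        text = res.summary()
        assert "epsilon" in text and "Support vectors" in text
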