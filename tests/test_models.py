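"""Solvers: soft-thresholding, smooth solutions, the four models, prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from modlasso import (
    ElasticNet,
    FitConfig,
    GraphNetLasso,
    Lasso,
    ModularityLasso,
    fit_glasso,
    fit_lasso,
    fit_mlasso,
    fit_model,
    mlasso_smooth_solution,
    modularity_penalty,
    predict,
    soft_threshold,
)

from conftest import random_graph


def ista_oracle(A, b, theta, n_iter=200_000, tol=1e-12):
    """Minimal independent proximal-gradient oracle for
    (1/2) w'Aw - b'w + theta ||w||_1 (no package code)."""
    L = np.max(np.linalg.eigvalsh(A))
    w = np.zeros_like(b)
    for _ in range(n_iter):
        z = w - (A @ w - b) / L
        w_new = np.sign(z) * np.maximum(np.abs(z) - theta / L, 0.0)
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w = w_new
    return w


class TestSoftThreshold:
    @pytest.mark.parametrize("v,theta,expected", [
        (1.5, 1.0, 0.5),
        (-0.3, 0.5, 0.0),
        (-2.0, 0.5, -1.5),
        (0.0, 0.0, 0.0),
    ])
    def test_scalar_cases(self, v, theta, expected):
        assert soft_threshold(np.array([v]), theta)[0] == pytest.approx(expected)

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=8),
           st.floats(0, 5))
    def test_shrinks_toward_zero_preserving_sign(self, values, theta):
        v = np.array(values)
        out = soft_threshold(v, theta)
        assert np.all(np.abs(out) <= np.abs(v) + 1e-12)
        assert np.all(out * v >= 0)


class TestModularityPenalty:
    def test_all_ones_vanishes(self, triangle_net):
        assert modularity_penalty(np.ones(3), triangle_net.B) == pytest.approx(0.0, abs=1e-10)

    def test_two_disjoint_edges_module_indicator(self, two_edges_net):
        # h = (1,1,1,1), m = 2; indicator of {A,B}:
        # B_AA + B_BB + 2 B_AB = -0.25 - 0.25 + 1.5 = 1.0
        i = two_edges_net.index_of
        w = np.zeros(4)
        w[i("A")] = w[i("B")] = 1.0
        assert modularity_penalty(w, two_edges_net.B) == pytest.approx(1.0)

    def test_triangle_pair_indicator(self, triangle_net):
        w = np.array([1.0, 1.0, 0.0])
        assert modularity_penalty(w, triangle_net.B) == pytest.approx(-2 / 3)

    def test_dimension_mismatch(self, triangle_net):
        with pytest.raises(ValueError, match="mismatch"):
            modularity_penalty(np.ones(4), triangle_net.B)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_ones_vanish_on_random_networks(self, seed):
        net = random_graph(np.random.default_rng(seed), 10)
        assert modularity_penalty(np.ones(10), net.B) == pytest.approx(0.0, abs=1e-9)


class TestSmoothSolution:
    def test_identity_design_recovers_y(self):
        y = np.array([1.0, -2.0, 3.0])
        w = mlasso_smooth_solution(np.eye(3), y, np.zeros((3, 3)), lam=0.0)
        np.testing.assert_allclose(w, y, atol=1e-10)

    def test_norm_decreases_with_lambda(self, triangle_net):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        norms = [np.linalg.norm(
            mlasso_smooth_solution(X, y, triangle_net.B_shifted, lam=lam))
            for lam in (0.0, 1.0, 10.0, 100.0, 1000.0)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_matches_direct_inverse_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        A = rng.normal(size=(6, 6))
        B = (A + A.T) / 2
        from modlasso import shift_negative_definite

        B_shift, _ = shift_negative_definite(B)
        lam = 0.5
        w = mlasso_smooth_solution(X, y, B_shift, lam=lam)
        oracle = np.linalg.inv(X.T @ X - lam * B_shift) @ X.T @ y
        np.testing.assert_allclose(w, oracle, atol=1e-8)

    def test_rejects_positive_definite_shift_violation(self):
        X = np.eye(3)
        y = np.ones(3)
        bad = np.eye(3) * 0.5  # max eigenvalue 0.5 > 1e-6
        with pytest.raises(ValueError, match="negative semidefinite"):
            mlasso_smooth_solution(X, y, bad, lam=1.0)

    def test_singular_system_advises_ridge(self):
        X = np.ones((3, 2))  # rank 1
        y = np.ones(3)
        with pytest.raises(ValueError, match="ridge"):
            mlasso_smooth_solution(X, y, np.zeros((2, 2)), lam=0.0, ridge=0.0)


def _orthonormal_design(rng, n, p):
    M = rng.normal(size=(n, p))
    Q, _ = np.linalg.qr(M)
    return Q[:, :p]


class TestSolverEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_equals_proximal_orthonormal_lam0(self, seed):
        """With no network penalty, one soft-threshold pass after the smooth
        solve is the exact L1 solution for orthonormal designs."""
        rng = np.random.default_rng(seed)
        n, p = 30, 8
        X = _orthonormal_design(rng, n, p)
        y = rng.normal(size=n)
        net = random_graph(rng, p)
        common = dict(lam=0.0, threshold=0.05, ridge=0.0, standardize=False)
        cf = ModularityLasso(network=net, solver="closed_form", **common).fit(X, y)
        px = ModularityLasso(network=net, solver="proximal", tol=1e-12,
                             max_iter=100_000, **common).fit(X, y)
        np.testing.assert_allclose(cf.coef_, px.coef_, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_equals_proximal_no_l1(self, seed):
        """With theta = 0 the problem is smooth, so both modes agree on any
        design and any penalty strength."""
        rng = np.random.default_rng(100 + seed)
        n, p = 20, 6
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        net = random_graph(rng, p)
        for cls in (ModularityLasso, GraphNetLasso):
            common = dict(lam=1.5, threshold=0.0, ridge=1e-10, standardize=False)
            cf = cls(network=net, solver="closed_form", **common).fit(X, y)
            px = cls(network=net, solver="proximal", tol=1e-12,
                     max_iter=200_000, **common).fit(X, y)
            np.testing.assert_allclose(cf.coef_, px.coef_, atol=1e-6)

    def test_proximal_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        n, p = 25, 8
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        net = random_graph(rng, p)
        est = GraphNetLasso(network=net, lam=0.8, threshold=2.0, ridge=0.0,
                            standardize=False, solver="proximal",
                            tol=1e-12, max_iter=200_000).fit(X, y)
        A = X.T @ X + 0.8 * net.L
        w = ista_oracle(A, X.T @ y, 2.0)
        np.testing.assert_allclose(est.coef_, w, atol=1e-6)

    def test_ols_reduction_lam0_theta0(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        net = random_graph(rng, 4)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        for cls in (ModularityLasso, GraphNetLasso):
            est = cls(network=net, lam=0.0, threshold=0.0, ridge=0.0,
                      standardize=False).fit(X, y)
            np.testing.assert_allclose(est.coef_, ols, atol=1e-8)


class TestLassoAndElasticNet:
    def test_scalar_kkt_solution(self):
        # min (1/2)||y - x w||^2 + theta |w|  with  x=(1,1)', y=(2,2)',
        # theta=1  =>  w = (x'y - theta)/x'x = 3/2
        X = np.array([[1.0], [1.0]])
        y = np.array([2.0, 2.0])
        est = Lasso(threshold=1.0, ridge=0.0, standardize=False,
                    solver="proximal", tol=1e-12, max_iter=100_000).fit(X, y)
        assert est.coef_[0] == pytest.approx(1.5, abs=1e-8)

    def test_full_shrinkage_above_dual_norm(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        theta = 1.01 * np.max(np.abs(X.T @ y))
        est = Lasso(threshold=theta, ridge=0.0, standardize=False,
                    solver="proximal", tol=1e-12, max_iter=10_000).fit(X, y)
        assert np.all(est.coef_ == 0)

    def test_theta0_ridge0_is_ols(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        est = Lasso(threshold=0.0, ridge=0.0, standardize=False,
                    solver="proximal", tol=1e-12, max_iter=100_000).fit(X, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(est.coef_, ols, atol=1e-7)

    def test_lasso_kkt_conditions(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        theta = 3.0
        est = Lasso(threshold=theta, ridge=0.0, standardize=False,
                    solver="proximal", tol=1e-12, max_iter=200_000).fit(X, y)
        grad = X.T @ (X @ est.coef_ - y)
        active = est.coef_ != 0
        np.testing.assert_allclose(grad[active],
                                   -theta * np.sign(est.coef_[active]), atol=1e-5)
        assert np.all(np.abs(grad[~active]) <= theta + 1e-5)

    def test_enet_ridge_shrinks_relative_to_lasso(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 6))
        y = X @ np.array([2.0, -1.5, 0, 0, 1.0, 0]) + 0.1 * rng.normal(size=25)
        kw = dict(threshold=0.5, standardize=False, solver="proximal",
                  tol=1e-10, max_iter=100_000)
        lasso = Lasso(ridge=0.0, **kw).fit(X, y)
        enet = ElasticNet(ridge=5.0, **kw).fit(X, y)
        assert np.linalg.norm(enet.coef_) < np.linalg.norm(lasso.coef_)


class TestFitBehaviour:
    def test_proximal_objective_non_increasing(self, small_bench):
        est = ModularityLasso(network=small_bench.network, lam=1.0,
                              threshold=5.0, solver="proximal", tol=1e-10,
                              max_iter=5000)
        est.fit(small_bench.dataset.X, small_bench.dataset.y)
        trace = np.array(est.objective_trace_)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_monotone_sparsity_in_theta_closed_form(self, small_bench):
        sizes = []
        for th in (0.0, 0.05, 0.1, 0.3, 1.0, 5.0):
            fit = fit_mlasso(small_bench.dataset, small_bench.network,
                             FitConfig(lam=1.0, threshold=th))
            sizes.append(fit.support_size)
        assert sizes == sorted(sizes, reverse=True)

    def test_nan_input_rejected(self, small_bench):
        X = small_bench.dataset.X.copy()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            ModularityLasso(network=small_bench.network).fit(
                X, small_bench.dataset.y)

    def test_network_feature_mismatch_rejected(self, small_bench, triangle_net):
        with pytest.raises(ValueError, match="feature"):
            ModularityLasso(network=triangle_net).fit(
                small_bench.dataset.X.to_numpy(), small_bench.dataset.y)

    def test_mlasso_benchmark_more_connected_than_lasso(self, default_bench):
        data, net = default_bench.dataset, default_bench.network
        lam_c = data.n / net.lambda_B
        prox = dict(solver="proximal", tol=1e-6, max_iter=6000)
        fm = fit_mlasso(data, net, FitConfig(lam=lam_c, threshold=30.0, **prox))
        fl = fit_lasso(data, FitConfig(threshold=30.0, **prox))
        k = min(fm.support_size, fl.support_size)
        top_l = fl.w.abs().sort_values(ascending=False).index[:k]
        e_m = net.graph.subgraph(list(fm.selected)[:]).number_of_edges()
        e_l = net.graph.subgraph(list(top_l)).number_of_edges()
        assert e_m > e_l


class TestPredict:
    def test_training_fit_matches_ols_predictions(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=20))
        fit = fit_lasso(_as_dataset(X, y), FitConfig(threshold=0.0, ridge=0.0))
        beta = np.linalg.lstsq(
            np.column_stack([np.ones(20), X.to_numpy()]), y, rcond=None)[0]
        np.testing.assert_allclose(
            predict(fit, X),
            np.column_stack([np.ones(20), X.to_numpy()]) @ beta, atol=1e-6)

    def test_zero_weights_predict_intercept(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=10) + 5.0)
        fit = fit_lasso(_as_dataset(X, y), FitConfig(threshold=1e6))
        assert fit.support_size == 0
        np.testing.assert_allclose(predict(fit, X), y.mean(), atol=1e-10)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        y = pd.Series(rng.normal(size=15))
        fit = fit_lasso(_as_dataset(X, y), FitConfig(threshold=0.01))
        shuffled = X[["d", "b", "a", "c"]]
        np.testing.assert_allclose(predict(fit, X), predict(fit, shuffled))

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=10))
        fit = fit_lasso(_as_dataset(X, y))
        bad = X.rename(columns={"c": "zz"})
        with pytest.raises(ValueError, match="missing"):
            predict(fit, bad)


def _as_dataset(X, y):
    from modlasso.simulate import MultiOmicDataset

    sd = X.std(axis=0, ddof=0)
    return MultiOmicDataset(
        X=X, y=y, layers={c: "gene" for c in X.columns},
        X_std=(X - X.mean()) / sd.where(sd > 0, 1.0))
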