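"""Normal equations, masking, ridge solver, and basis compression."""

import numpy as np
import pytest
from scipy.optimize import minimize

from varxgranger import (EstimationError, FitConfig, MultiSeries,
                         build_normal_equations, fit_varx, gaussian_basis,
                         residual_stats, ridge_solve, simulate_varx)
from varxgranger.estimation import build_design


def dense_design_oracle(data, n_a, n_b):
    """Independent dense construction: explicit per-sample loop building
    phi(t) and checking the validity window rule."""
    T, d_y, d_x = data.T, data.d_y, data.d_x
    N = d_y * n_a + d_x * n_b
    seg = np.searchsorted(data.segment_starts, np.arange(T), side="right") - 1
    rows, targets = [], []
    min_depth = max(n_a, n_b - 1, 0)
    for t in range(T):
        start = data.segment_starts[seg[t]]
        if t - start < min_depth:
            continue
        phi = []
        for j in range(d_y):
            phi.extend(data.Y[t - l, j] for l in range(1, n_a + 1))
        for j in range(d_x):
            phi.extend(data.X[t - l, j] for l in range(n_b))
        phi = np.array(phi)
        if np.isfinite(phi).all() and np.isfinite(data.Y[t]).all():
            rows.append(phi)
            targets.append(data.Y[t])
    X = np.array(rows).reshape(-1, N)
    Y = np.array(targets).reshape(-1, d_y)
    return X, Y


class TestGaussianBasis:
    def test_small_width_approaches_identity(self):
        W = gaussian_basis(5, 5, width=0.05).W
        np.testing.assert_allclose(W, np.eye(5), atol=1e-8)

    def test_long_filter_compression_shape(self):
        bs = gaussian_basis(30, 20)
        assert bs.W.shape == (30, 20)
        assert (bs.W.sum(axis=1) > 0).all()          # no coverage gaps
        np.testing.assert_allclose(bs.W.max(axis=0), 1.0)  # unit-max columns

    def test_projection_reconstructs_smooth_filter(self):
        """A smooth lag filter projected through the basis by direct
        pseudo-inverse is recovered with < 5% relative error."""
        n_b = 30
        lags = np.arange(n_b)
        target = np.exp(-0.5 * ((lags - 12.0) / 4.0) ** 2)
        W = gaussian_basis(n_b, 15).W
        recon = W @ np.linalg.lstsq(W, target, rcond=None)[0]
        rel = np.linalg.norm(recon - target) / np.linalg.norm(target)
        assert rel < 0.05

    def test_rejects_more_bases_than_lags(self):
        with pytest.raises(ValueError):
            gaussian_basis(4, 5)


class TestMasking:
    def test_warmup_samples_dropped(self, rng):
        data = MultiSeries(Y=rng.standard_normal((100, 2)),
                           X=rng.standard_normal((100, 1)))
        ne = build_normal_equations(data, FitConfig(n_a=2, n_b=2))
        assert ne.T_used == 98            # only the first max(n_a, n_b-1) lack history

    def test_single_missing_value_drops_its_window(self, rng):
        Y = rng.standard_normal((200, 2))
        X = rng.standard_normal((200, 1))
        Y[50, 1] = np.nan
        data = MultiSeries(Y=Y, X=X)
        ne = build_normal_equations(data, FitConfig(n_a=3, n_b=2))
        # samples 50..53 have the NaN in target or lag window
        assert ne.T_used == 200 - 3 - 4

    @pytest.mark.parametrize("trial", range(10))
    def test_validity_mask_matches_per_sample_oracle(self, trial):
        """Random missingness and segmentation: T_used and both
        cross-products agree with the explicit dense loop."""
        rng = np.random.default_rng(100 + trial)
        T = 120
        Y = rng.standard_normal((T, 2))
        X = rng.standard_normal((T, 1))
        miss = rng.random((T, 2)) < 0.03
        Y[miss] = np.nan
        segs = [0] + sorted(rng.choice(np.arange(10, T - 10), size=2,
                                       replace=False).tolist())
        data = MultiSeries(Y=Y, X=X, segment_starts=segs)
        n_a, n_b = 2, 3
        ne = build_normal_equations(data, FitConfig(n_a=n_a, n_b=n_b))
        Xd, Yd = dense_design_oracle(data, n_a, n_b)
        assert ne.T_used == Xd.shape[0]
        np.testing.assert_allclose(ne.R_xx, Xd.T @ Xd, rtol=1e-10)
        np.testing.assert_allclose(ne.R_xy, Xd.T @ Yd, rtol=1e-10)

    def test_no_valid_samples_is_an_error(self, rng):
        data = MultiSeries(Y=rng.standard_normal((5, 1)))
        with pytest.raises(EstimationError, match="no valid samples"):
            build_normal_equations(data, FitConfig(n_a=10))

    def test_all_missing_variable_is_named(self, rng):
        Y = rng.standard_normal((50, 2))
        Y[:, 1] = np.nan
        with pytest.raises(EstimationError, match="y2"):
            build_normal_equations(MultiSeries(Y=Y), FitConfig(n_a=1))


class TestRidgeSolve:
    def test_ols_matches_dense_least_squares(self, simulated_data):
        ne = build_normal_equations(simulated_data, FitConfig(n_a=2, n_b=3))
        H = ridge_solve(ne, gamma=0.0)
        Xd, Yd = dense_design_oracle(simulated_data, 2, 3)
        H_dense = np.linalg.lstsq(Xd, Yd, rcond=None)[0]
        np.testing.assert_allclose(H, H_dense, rtol=1e-8, atol=1e-10)

    def test_large_gamma_shrinks_to_zero(self, simulated_data):
        ne = build_normal_equations(simulated_data, FitConfig(n_a=2, n_b=3))
        H = ridge_solve(ne, gamma=1e12)
        assert np.abs(H).max() < 1e-6

    def test_matches_numeric_minimizer_of_penalized_loss(self):
        """On a 5-predictor toy problem the closed form minimizes
        ||Y - XH||^2 + gamma ||Gamma^{1/2} H||^2 (checked by BFGS)."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 5)) * np.array([1.0, 2.0, 0.5, 1.5, 3.0])
        Yv = rng.standard_normal((40, 1))
        R_xx, R_xy = X.T @ X, X.T @ Yv
        gamma = 0.3
        H = ridge_solve(R_xx, R_xy, gamma=gamma)

        G = np.diag(R_xx)

        def loss(h):
            r = Yv[:, 0] - X @ h
            return r @ r + gamma * h @ (G * h)

        res = minimize(loss, np.zeros(5), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(H[:, 0], res.x, atol=1e-5)
        assert loss(H[:, 0]) <= res.fun + 1e-9

    def test_singular_system_warns_and_falls_back(self):
        R_xx = np.ones((3, 3))                 # rank 1
        R_xy = np.ones((3, 1))
        with pytest.warns(RuntimeWarning, match="singular"):
            H = ridge_solve(R_xx, R_xy, gamma=0.0)
        assert np.isfinite(H).all()


class TestResidualStats:
    def test_zero_coefficients_give_total_variance(self, simulated_data):
        ne = build_normal_equations(simulated_data, FitConfig(n_a=2, n_b=3))
        sigma2, _, _ = residual_stats(ne, np.zeros((ne.N, 2)))
        np.testing.assert_allclose(sigma2, ne.R_yy_diag / ne.T_used)

    def test_matches_explicit_residuals(self, simulated_data):
        ne = build_normal_equations(simulated_data, FitConfig(n_a=2, n_b=3))
        H = ridge_solve(ne, gamma=0.0)
        sigma2, _, R_xe = residual_stats(ne, H)
        Xd, Yd = dense_design_oracle(simulated_data, 2, 3)
        resid = Yd - Xd @ H
        np.testing.assert_allclose(sigma2, np.mean(resid ** 2, axis=0),
                                   rtol=1e-8)
        np.testing.assert_allclose(R_xe, np.zeros_like(R_xe), atol=1e-6)

    def test_noiseless_fit_leaves_no_residual(self, rng, stable_filters):
        x = rng.standard_normal((2000, 1))
        y = simulate_varx(stable_filters, x=x, e=np.zeros((2000, 2)))
        data = MultiSeries(Y=y, X=x)
        ne = build_normal_equations(data, FitConfig(n_a=2, n_b=3))
        sigma2, _, _ = residual_stats(ne, ridge_solve(ne))
        assert sigma2.max() < 1e-12


class TestUnpack:
    def test_roundtrip_recovers_generating_filters(self, rng, stable_filters):
        x = rng.standard_normal((5000, 1))
        y = simulate_varx(stable_filters, x=x, e=np.zeros((5000, 2)))
        est, _, _, _ = fit_varx(MultiSeries(Y=y, X=x), FitConfig(n_a=2, n_b=3))
        np.testing.assert_allclose(est.A, stable_filters.A, atol=1e-6)
        np.testing.assert_allclose(est.B, stable_filters.B, atol=1e-6)

    def test_identity_like_basis_matches_unconstrained(self, simulated_data):
        cfg = FitConfig(n_a=2, n_b=3)
        est_plain, _, _, _ = fit_varx(simulated_data, cfg)
        bs = gaussian_basis(3, 3, width=0.05)
        est_basis, _, _, _ = fit_varx(simulated_data, cfg, basis=bs)
        np.testing.assert_allclose(est_basis.B, est_plain.B, atol=1e-5)
        np.testing.assert_allclose(est_basis.A, est_plain.A, atol=1e-5)

    def test_basis_fit_recovers_smooth_filter(self, rng):
        """With B a smooth bump over 20 lags, the compressed fit (8
        bases) recovers it closely on long data."""
        lags = np.arange(20)
        B = np.exp(-0.5 * ((lags - 8.0) / 3.0) ** 2)[:, None, None]
        truth_A = np.array([[[0.3]]])
        f = __import__("varxgranger").VARXFilters(A=truth_A, B=B)
        x = rng.standard_normal((20000, 1))
        y = simulate_varx(f, x=x, rng=rng)
        est, _, _, _ = fit_varx(MultiSeries(Y=y, X=x),
                                FitConfig(n_a=1, n_b=20, n_basis=8))
        assert np.abs(est.B - B).max() < 0.1 * B.max()


def test_consistency_error_shrinks_with_T(stable_filters):
    errs = []
    for T in (500, 5000):
        rng = np.random.default_rng(77)
        x = rng.standard_normal((T, 1))
        y = simulate_varx(stable_filters, x=x, rng=rng)
        est, _, _, _ = fit_varx(MultiSeries(Y=y, X=x), FitConfig(n_a=2, n_b=3))
        errs.append(max(np.abs(est.A - stable_filters.A).max(),
                        np.abs(est.B - stable_filters.B).max()))
    assert errs[1] < errs[0]


def test_pure_ma_fit_predicts_by_direct_convolution(rng):
    """n_a = 0 reduces the model to an MA temporal-response-function fit:
    predictions equal the convolution of x with the estimated B."""
    B = np.array([[[1.0]], [[0.6]], [[0.2]]])
    f = __import__("varxgranger").VARXFilters(A=np.zeros((0, 1, 1)), B=B)
    x = rng.standard_normal((3000, 1))
    y = simulate_varx(f, x=x, rng=rng)
    data = MultiSeries(Y=y, X=x)
    est, ne, H_hat, _ = fit_varx(data, FitConfig(n_a=0, n_b=3))
    Phi, _, valid = build_design(data, 0, 3)
    pred_design = Phi[valid] @ H_hat
    pred_conv = np.convolve(x[:, 0], est.B[:, 0, 0])[:3000][valid]
    np.testing.assert_allclose(pred_design[:, 0], pred_conv, rtol=1e-10)
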