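"""LAR-LASSO path correctness against closed forms and convex-optimisation
oracles, plus the path's structural invariants."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from larmap.design import StandardizationTransform, standardize_pair
from larmap.lars import (PenalizedFitSpec, coefficients_at_l1, lar_lasso_path,
                         predict)

from conftest import standardized_instance


def cd_lasso_oracle(X, y, lam):
    """Coordinate-descent solution of min ||y - Xb||^2 + 2*lam*|b|_1.

    scikit-learn's Lasso minimises (1/2n)||y - Xb||^2 + alpha |b|_1, so the
    matching alpha is lam / n.
    """
    n = X.shape[0]
    model = Lasso(alpha=lam / n, fit_intercept=False, max_iter=1_000_000,
                  tol=1e-14)
    model.fit(X, y)
    return model.coef_


def kkt_violation(X, y, beta, lam):
    """Max violation of the LASSO stationarity conditions at penalty lam."""
    g = X.T @ (y - X @ beta)     # = lam * sign(beta_j) on the active set
    active = beta != 0
    v = 0.0
    if active.any():
        v = max(v, float(np.abs(g[active] - lam * np.sign(beta[active])).max()))
    if (~active).any():
        v = max(v, float(np.maximum(np.abs(g[~active]) - lam, 0.0).max()))
    return v


class TestClosedForms:
    def test_orthonormal_soft_thresholding(self, rng):
        A = rng.standard_normal((40, 8))
        A -= A.mean(axis=0)
        X = np.linalg.qr(A)[0][:, :8]
        y = rng.standard_normal(40)
        y -= y.mean()
        c0 = X.T @ y
        path = lar_lasso_path(X, y)
        for step in path.steps:
            expected = np.sign(c0) * np.maximum(np.abs(c0) - step.max_abs_corr, 0.0)
            np.testing.assert_allclose(step.beta, expected, atol=1e-9)

    def test_orthogonal_response_gives_null_path(self, rng):
        X, y = standardized_instance(0, 25, 5)
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]   # project out X
        path = lar_lasso_path(X, y)
        assert np.abs(path.betas()).max() < 1e-10

    def test_full_path_reaches_ols_when_p_less_than_n(self, rng):
        X, y = standardized_instance(3, 40, 7)
        path = lar_lasso_path(X, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(path.steps[-1].beta, ols, atol=1e-8)
        assert path.steps[-1].max_abs_corr < 1e-8


class TestOracleEquivalence:
    @pytest.mark.parametrize("n,p,rho", [(15, 5, 0.0), (15, 5, 0.9),
                                         (35, 5, 0.0), (35, 5, 0.9),
                                         (15, 60, 0.0), (15, 60, 0.9),
                                         (35, 60, 0.0), (35, 60, 0.9)])
    def test_breakpoints_match_cd_oracle(self, n, p, rho):
        """Central check: >= 50 instances spanning the n/p/collinearity grid.

        Each breakpoint with a well-conditioned penalty (bounded away from
        the non-unique near-zero-lambda regime) must match the independent
        coordinate-descent solution to 1e-6; every breakpoint, including
        the small-lambda ones, must satisfy the LASSO KKT conditions.
        """
        for seed in range(7):
            X, y = standardized_instance(1000 * seed + n + p, n, p, rho)
            path = lar_lasso_path(X, y)
            lam_max = path.steps[0].max_abs_corr
            for step in path.steps:
                lam = step.max_abs_corr
                assert kkt_violation(X, y, step.beta, lam) < 1e-8
                if lam >= 1e-3 * lam_max and (p < n or lam >= 1e-2 * lam_max):
                    oracle = cd_lasso_oracle(X, y, lam)
                    assert np.abs(oracle - step.beta).max() < 1e-6

    def test_drop_steps_occur_and_match_oracle(self):
        """Sign-crossing removals are exercised, not just theoretical."""
        total_drops = 0
        for seed in range(60):
            X, y = standardized_instance(seed, 12, 8, 0.0, k_signal=4, noise=1.0)
            path = lar_lasso_path(X, y)
            drops = [s for s in path.steps if s.event == "drop"]
            total_drops += len(drops)
            lam_max = path.steps[0].max_abs_corr
            for step in drops:
                if step.max_abs_corr >= 1e-2 * lam_max:
                    oracle = cd_lasso_oracle(X, y, step.max_abs_corr)
                    assert np.abs(oracle - step.beta).max() < 1e-6
        assert total_drops >= 5


class TestPathInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_equicorrelation_and_monotone_penalty(self, seed):
        X, y = standardized_instance(seed, 30, 12, 0.5)
        path = lar_lasso_path(X, y)
        corrs = [s.max_abs_corr for s in path.steps]
        assert all(b <= a + 1e-9 for a, b in zip(corrs, corrs[1:]))
        for step in path.steps:
            if not step.active:
                continue
            resid_corr = np.abs(X.T @ (y - X @ step.beta))
            active = np.array(step.active)
            spread = resid_corr[active].max() - resid_corr[active].min()
            assert spread <= 1e-8
            inactive = np.setdiff1d(np.arange(X.shape[1]), active)
            if inactive.size:
                assert resid_corr[inactive].max() <= resid_corr[active].max() + 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_active_set_changes_by_one_and_sign_consistency(self, seed):
        X, y = standardized_instance(100 + seed, 25, 10, 0.3)
        path = lar_lasso_path(X, y)
        prev = set()
        for step in path.steps[1:]:
            cur = set(step.active)
            if step.event in ("add", "drop"):
                assert len(cur ^ prev) == 1
            prev = cur
        # entering coefficient signs match the entry correlation sign
        beta_prev = path.steps[0].beta
        for k, step in enumerate(path.steps[1:], 1):
            if step.event == "add":
                j = step.term
                c = X[:, j] @ (y - X @ step.beta)
                nxt = path.steps[k + 1] if k + 1 < len(path.steps) else None
                if nxt is not None and nxt.beta[j] != 0:
                    assert np.sign(nxt.beta[j]) == np.sign(c)

    def test_degrees_of_freedom_cap(self):
        X, y = standardized_instance(7, 10, 40, 0.0)
        path = lar_lasso_path(X, y)
        assert max(len(s.active) for s in path.steps) <= 9

    def test_unstandardized_input_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        with pytest.raises(ValueError, match="standardized"):
            lar_lasso_path(X, y - y.mean())

    def test_threshold_stops_early(self):
        X, y = standardized_instance(11, 30, 8)
        full = lar_lasso_path(X, y)
        lam_mid = full.steps[len(full.steps) // 2].max_abs_corr
        stopped = lar_lasso_path(X, y, PenalizedFitSpec(corr_threshold=lam_mid))
        assert stopped.steps[-1].max_abs_corr <= lam_mid + 1e-12
        assert len(stopped.steps) <= len(full.steps)

    def test_ridge_exponent_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            PenalizedFitSpec(gamma=2)


class TestInterpolationAndPrediction:
    def test_l1_interpolation_endpoints_and_midpoint(self):
        X, y = standardized_instance(21, 30, 6)
        path = lar_lasso_path(X, y)
        np.testing.assert_allclose(coefficients_at_l1(path, 0.0),
                                   np.zeros(6), atol=0)
        for step in path.steps:
            np.testing.assert_allclose(coefficients_at_l1(path, step.l1_norm),
                                       step.beta, atol=1e-10)
        a, b = path.steps[2], path.steps[3]
        mid = 0.5 * (a.l1_norm + b.l1_norm)
        beta_mid = coefficients_at_l1(path, mid)
        # the interpolated solution solves the lasso at its implied penalty
        lam_mid = 0.5 * (a.max_abs_corr + b.max_abs_corr)
        oracle = cd_lasso_oracle(X, y, lam_mid)
        assert np.abs(oracle - beta_mid).max() < 1e-6
        with pytest.raises(ValueError, match="outside"):
            coefficients_at_l1(path, path.steps[-1].l1_norm * 2 + 1)

    def test_zero_coefficients_predict_training_mean(self, rng):
        X_raw = rng.standard_normal((15, 4)) * 3 + 1
        y_raw = rng.standard_normal(15) + 5
        _, _, _, tr = standardize_pair(X_raw, y_raw)
        pred = predict(np.zeros(4), tr, X_raw)
        np.testing.assert_allclose(pred, np.full(15, y_raw.mean()))

    def test_full_path_prediction_equals_ols_fit(self, rng):
        X_raw = rng.standard_normal((30, 5)) * 2 + 4
        y_raw = rng.standard_normal(30) + 2
        Xs, ys, _, tr = standardize_pair(X_raw, y_raw)
        path = lar_lasso_path(Xs, ys)
        pred = predict(path.steps[-1].beta, tr, X_raw)
        ols_fit = ys - (ys - Xs @ np.linalg.lstsq(Xs, ys, rcond=None)[0])
        np.testing.assert_allclose(pred, y_raw.mean() + ols_fit, atol=1e-8)

    def test_perfect_single_covariate_fit(self):
        X_raw = np.array([[0.0], [1.0], [2.0]])
        y_raw = np.array([0.0, 1.0, 2.0])
        Xs, ys, _, tr = standardize_pair(X_raw, y_raw)
        path = lar_lasso_path(Xs, ys)
        np.testing.assert_allclose(predict(path.steps[-1].beta, tr, X_raw),
                                   y_raw, atol=1e-10)
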