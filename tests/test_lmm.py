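"""Mixed-model machinery: design building, REML, GLS/BLUP, model choice."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from prevadjust import CellTable, ModelDesign, compare_models, gls_blup
from prevadjust.datamodel import MEMBER_AUX_PREFIX, NATIONAL_AUX_PREFIX
from prevadjust.lmm import (
    BlockedModel,
    DesignError,
    FitError,
    build_design,
    fit_region_design,
    fit_reml,
)

from conftest import build_tiny_frame


def dense_gls_blup(y, X, Z, codes, psi, sigma2):
    """Brute-force dense-matrix GLS/BLUP oracle."""
    n = len(y)
    D = int(codes.max()) + 1
    Q = Z.shape[1]
    Zf = np.zeros((n, D * Q))
    for i, c in enumerate(codes):
        Zf[i, c * Q:(c + 1) * Q] = Z[i]
    Psi = np.kron(np.eye(D), np.atleast_2d(psi))
    V = Zf @ Psi @ Zf.T + sigma2 * np.eye(n)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    b = Psi @ Zf.T @ Vi @ (y - X @ beta)
    return beta, b.reshape(D, Q)


def random_instance(seed, max_rows=200, max_p=6, max_q=2):
    rng = np.random.default_rng(seed)
    Q = int(rng.integers(1, max_q + 1))
    P = int(rng.integers(1, max_p + 1))
    D = int(rng.integers(3, 9))
    sizes = rng.integers(Q + 1, max(Q + 2, max_rows // D), D)
    codes = np.repeat(np.arange(D), sizes)
    n = len(codes)
    X = rng.normal(size=(n, P))
    Z = rng.normal(size=(n, Q))
    y = rng.normal(size=n)
    A = rng.normal(size=(Q, Q))
    psi = A @ A.T + 0.05 * np.eye(Q)
    sigma2 = 0.3 + rng.random()
    return y, X, Z, codes, psi, sigma2


class TestBuildDesign:
    def test_random_intercept_block_structure(self, tiny_table):
        d = ModelDesign(fixed_effects=["intercept", "cell_size"])
        dm = build_design(tiny_table, 1, d, "member")
        assert dm.n_rows == 16 and dm.n_random == 1
        assert np.all(dm.Z == 1.0)
        assert dm.district_ids == [(1, 1), (1, 2)]

    def test_member_build_skips_empty_cells(self, tiny_frame):
        tiny_frame.loc[0, ["n_member", "y_member"]] = 0
        table = CellTable(tiny_frame)
        d = ModelDesign(fixed_effects=["intercept", "cell_size"])
        dm = build_design(table, 1, d, "member")
        assert dm.n_rows == 15
        dn = build_design(table, 1, d, "national")
        assert dn.n_rows == 16 and dn.y is None

    def test_age_dummies_full_rank(self, tiny_table):
        d = ModelDesign(fixed_effects=["intercept", "age_group", "sex"])
        dm = build_design(tiny_table, 1, d, "member")
        assert dm.columns == ["intercept", "age[II]", "age[III]", "age[IV]", "sex[male]"]
        assert np.linalg.matrix_rank(dm.X) == 5

    def test_collinear_columns_named(self, tiny_frame):
        lab = "E11_secondary"
        tiny_frame[MEMBER_AUX_PREFIX + "DUP_main"] = 2.0 * tiny_frame[MEMBER_AUX_PREFIX + lab]
        tiny_frame[NATIONAL_AUX_PREFIX + "DUP_main"] = 2.0 * tiny_frame[NATIONAL_AUX_PREFIX + lab]
        table = CellTable(tiny_frame)
        d = ModelDesign(fixed_effects=["intercept", lab, "DUP_main"])
        with pytest.raises(DesignError, match="collinear"):
            build_design(table, 1, d, "member")

    def test_member_and_national_use_matching_columns(self, tiny_table):
        d = ModelDesign(fixed_effects=["intercept", "cell_size", "E11_secondary"])
        dm = build_design(tiny_table, 1, d, "member")
        dn = build_design(tiny_table, 1, d, "national")
        assert dm.columns == dn.columns
        assert dm.X[0, 1] != dn.X[0, 1]  # member vs national cell size


class TestRemlClosedForm:
    @pytest.mark.parametrize("m", [5, 20])
    @pytest.mark.parametrize("n_per", [4, 10])
    def test_balanced_one_way_matches_anova_estimators(self, m, n_per):
        """On a balanced one-way random-intercept layout the REML variance
        components equal the closed-form ANOVA estimators."""
        rng = np.random.default_rng(1000 + 10 * m + n_per)
        b = rng.normal(0, 1.8, m)
        y = (b[:, None] + rng.normal(0, 1.2, (m, n_per))).ravel()
        X = np.ones((m * n_per, 1))
        Z = np.ones((m * n_per, 1))
        codes = np.repeat(np.arange(m), n_per)
        fit = fit_reml(y, X, Z, codes)
        grp = y.reshape(m, n_per)
        msw = ((grp - grp.mean(1, keepdims=True)) ** 2).sum() / (m * (n_per - 1))
        msb = n_per * ((grp.mean(1) - y.mean()) ** 2).sum() / (m - 1)
        psi_cf = max(0.0, (msb - msw) / n_per)
        assert fit.sigma2_hat == pytest.approx(msw, rel=1e-6)
        assert fit.psi_hat[0, 0] == pytest.approx(psi_cf, rel=1e-6)
        assert fit.converged

    def test_zero_psi_truth_hits_boundary_and_ols(self):
        rng = np.random.default_rng(3)
        n, P = 120, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, P - 1))])
        y = X @ np.array([2.0, -1.0, 0.5]) + rng.normal(0, 1.0, n)
        codes = np.repeat(np.arange(12), 10)
        fit = fit_reml(y, X, np.ones((n, 1)), codes)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.psi_hat[0, 0] <= 1e-6 * fit.sigma2_hat
        np.testing.assert_allclose(fit.beta_hat, ols, rtol=1e-6)

    def test_too_few_rows_rejected(self):
        with pytest.raises(FitError, match="too few rows"):
            fit_reml(np.zeros(3), np.ones((3, 2)), np.ones((3, 1)), np.array([0, 0, 1]))


class TestGlsBlup:
    def test_zero_psi_reduces_to_ols(self):
        y, X, Z, codes, _, _ = random_instance(5)
        beta, b = gls_blup(y, X, Z, codes, np.zeros((Z.shape[1],) * 2), 1.3)
        np.testing.assert_allclose(beta, np.linalg.lstsq(X, y, rcond=None)[0], rtol=1e-10)
        assert np.all(b == 0.0)

    def test_sigma2_zero_rejected(self):
        y, X, Z, codes, psi, _ = random_instance(6)
        with pytest.raises(ValueError, match="sigma2"):
            gls_blup(y, X, Z, codes, psi, 0.0)

    @given(st.integers(0, 10_000))
    def test_matches_dense_oracle(self, seed):
        """Blocked GLS/BLUP equals the brute-force dense formulas."""
        y, X, Z, codes, psi, sigma2 = random_instance(seed)
        beta, b = gls_blup(y, X, Z, codes, psi, sigma2)
        beta_o, b_o = dense_gls_blup(y, X, Z, codes, psi, sigma2)
        np.testing.assert_allclose(beta, beta_o, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(b, b_o, rtol=1e-8, atol=1e-10)

    def test_interpolation_limit_reproduces_response(self):
        """With one row per district and a dominant random effect the
        fitted values approach the observed response."""
        rng = np.random.default_rng(11)
        n = 6
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        Z = np.ones((n, 1))
        codes = np.arange(n)
        beta, b = gls_blup(y, X, Z, codes, np.array([[1e10]]), 1.0)
        np.testing.assert_allclose(X @ beta + b[codes, 0], y, atol=1e-6)


class TestInvariances:
    def test_row_and_block_reordering(self):
        y, X, Z, codes, psi, sigma2 = random_instance(42)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        f1 = fit_reml(y, X, Z, codes)
        f2 = fit_reml(y[perm], X[perm], Z[perm], codes[perm])
        np.testing.assert_allclose(f1.beta_hat, f2.beta_hat, rtol=1e-6)
        np.testing.assert_allclose(f1.sigma2_hat, f2.sigma2_hat, rtol=1e-6)
        np.testing.assert_allclose(f1.fitted[perm], f2.fitted, rtol=1e-6, atol=1e-10)

    @given(st.integers(0, 5000))
    def test_reml_invariant_under_reparameterization(self, seed):
        """The restricted likelihood and variance estimates are unchanged
        by a full-rank linear reparameterization of the fixed effects."""
        rng = np.random.default_rng(seed)
        n, P = 60, 3
        codes = np.repeat(np.arange(6), 10)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, P - 1))])
        b = rng.normal(0, 1.0, 6)
        y = X @ rng.normal(size=P) + b[codes] + rng.normal(0, 0.7, n)
        T = rng.normal(size=(P, P)) + 3 * np.eye(P)
        f1 = fit_reml(y, X, np.ones((n, 1)), codes)
        f2 = fit_reml(y, X @ T, np.ones((n, 1)), codes)
        assert f1.reml_loglik == pytest.approx(f2.reml_loglik, rel=1e-6, abs=1e-6)
        assert f1.sigma2_hat == pytest.approx(f2.sigma2_hat, rel=1e-5)
        np.testing.assert_allclose(f1.fitted, f2.fitted, rtol=1e-5, atol=1e-8)


class TestAgainstStatsmodels:
    def test_variance_components_match_mixedlm(self):
        """Independent REML implementation (statsmodels MixedLM) agrees on
        fixed effects and variance components."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        D, C = 12, 8
        codes = np.repeat(np.arange(D), C)
        n = D * C
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        b = rng.normal(0, 1.2, D)
        y = X @ np.array([1.0, 0.5, -0.3]) + b[codes] + rng.normal(0, 0.8, n)
        fit = fit_reml(y, X, np.ones((n, 1)), codes)
        mf = sm.regression.mixed_linear_model.MixedLM(y, X, groups=codes).fit(reml=True)
        np.testing.assert_allclose(fit.beta_hat, mf.fe_params, rtol=1e-5)
        assert fit.sigma2_hat == pytest.approx(mf.scale, rel=1e-4)
        assert fit.psi_hat[0, 0] == pytest.approx(float(np.asarray(mf.cov_re)[0, 0]), rel=1e-3)


class TestModelComparison:
    def _fit_pair(self, seed=0, noise_col=True):
        rng = np.random.default_rng(seed)
        D, C = 12, 8
        codes = np.repeat(np.arange(D), C)
        n = D * C
        x1 = rng.normal(size=n)
        Xs = np.column_stack([np.ones(n), x1])
        b = rng.normal(0, 0.8, D)
        y = 1.0 + 0.6 * x1 + b[codes] + rng.normal(0, 1.0, n)
        Xl = np.column_stack([Xs, rng.normal(size=n)])
        fs = fit_reml(y, Xs, np.ones((n, 1)), codes, fixed_names=["intercept", "x1"])
        fl = fit_reml(y, Xl, np.ones((n, 1)), codes, fixed_names=["intercept", "x1", "noise"])
        return fs, fl

    def test_identical_fits_give_zero_lr_and_equal_criterion(self):
        fs, _ = self._fit_pair()
        cmp = compare_models(fs, fs)
        assert cmp.lr_stat == 0.0
        assert cmp.caic_small == cmp.caic_large

    def test_effective_df_reduces_to_p_without_random_effects(self):
        rng = np.random.default_rng(2)
        n = 80
        codes = np.repeat(np.arange(8), 10)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 1.0, n)  # no group effect
        fit = fit_reml(y, X, np.ones((n, 1)), codes)
        if fit.boundary:
            assert fit.effective_df == pytest.approx(X.shape[1], abs=1e-8)
        else:
            assert fit.effective_df < X.shape[1] + 2

    def test_non_nested_designs_flag_anova(self):
        fs, fl = self._fit_pair()
        fs.fixed_names = ["intercept", "other"]
        cmp = compare_models(fs, fl)
        assert cmp.anova_error is not None
        assert np.isfinite(cmp.caic_small) and np.isfinite(cmp.caic_large)

    def test_bic_penalty_rejects_noise_more_often_than_aic(self):
        """Adding a pure-noise fixed effect: the BIC-strength conditional
        criterion prefers the smaller model in a clear majority of
        replicates and at least as often as the AIC-strength variant."""
        n_small_bic = n_small_aic = 0
        reps = 100
        for r in range(reps):
            fs, fl = self._fit_pair(seed=900 + r)
            n_small_bic += compare_models(fs, fl, penalty="bic").preferred == "small"
            n_small_aic += compare_models(fs, fl, penalty="aic").preferred == "small"
        assert n_small_bic / reps > 0.7
        assert n_small_bic > n_small_aic
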