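import numpy as np
import pytest
from scipy import stats

import voxgc as v
from voxgc.datasets import lagged_arrays

from conftest import make_regression


class TestOlsRefit:
    def test_empty_active_set(self):
        pr = make_regression(20, 3, seed=0)
        b, t, p, df = v.ols_refit(pr, [])
        assert b.size == t.size == p.size == 0
        assert df == 20

    def test_perfect_fit_sentinel(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        pr = v.RegressionProblem(x[:, None], 2.0 * x, [(0, 1)],
                                 np.zeros(30, dtype=int), np.arange(30))
        with pytest.warns(UserWarning, match="perfect fit"):
            b, t, p, df = v.ols_refit(pr, [0])
        assert b[0] == pytest.approx(2.0)
        assert np.isposinf(t[0])
        assert p[0] == 0.0

    def test_matches_normal_equations_oracle(self):
        pr = make_regression(40, 3, seed=5, beta=np.array([0.5, -0.2, 0.0]), noise_sd=0.3)
        b, t, p, df = v.ols_refit(pr, [0, 1, 2])
        X, y = pr.design, pr.response
        XtX_inv = np.linalg.inv(X.T @ X)
        b_or = XtX_inv @ X.T @ y
        resid = y - X @ b_or
        sigma2 = resid @ resid / (40 - 3)
        se = np.sqrt(np.diag(sigma2 * XtX_inv))
        np.testing.assert_allclose(b, b_or, atol=1e-10)
        np.testing.assert_allclose(t, b_or / se, atol=1e-10)
        np.testing.assert_allclose(p, 2 * stats.t.sf(np.abs(b_or / se), 37), atol=1e-12)
        assert df == 37

    def test_collinear_columns_dropped_lowest_kept(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 2))
        X = np.column_stack([x[:, 0], x[:, 0] * 2.0, x[:, 1]])  # col 1 duplicates col 0
        y = x @ np.array([1.0, 0.5]) + rng.normal(0, 0.1, 30)
        pr = v.RegressionProblem(X, y, [(j, 1) for j in range(3)],
                                 np.zeros(30, dtype=int), np.arange(30))
        with pytest.warns(UserWarning, match="collinear"):
            b, t, p, df = v.ols_refit(pr, [0, 1, 2])
        assert b[1] == 0.0 and p[1] == 1.0   # duplicate dropped
        assert b[0] != 0.0                   # lowest index kept
        assert df == 30 - 2


def chain_model():
    """x drives y drives z, all with self-lags; no direct x→z coupling."""
    B = np.array([[0.5, 0.0, 0.0],
                  [0.5, 0.5, 0.0],
                  [0.0, 0.5, 0.5]])
    return v.MvarModel(coeffs=[B], partition=(1, 2), innovation_sd=0.1)


class TestFitLassoGc:
    def test_unselected_entries_are_null(self, small_dataset):
        _, data = small_dataset
        est = v.fit_lasso_gc(data, seed=3)
        off = ~est.selected
        assert np.all(est.b_hat[off] == 0)
        assert np.all(est.t_scores[off] == 0)
        assert np.all(est.p_values[off] == 1)

    def test_p_values_consistent_with_t(self, small_dataset):
        _, data = small_dataset
        est = v.fit_lasso_gc(data, seed=3)
        for i in range(7):
            sel = est.selected[i]
            if sel.any():
                expect = 2 * stats.t.sf(np.abs(est.t_scores[i, sel]), est.row_df[i])
                np.testing.assert_allclose(est.p_values[i, sel], expect, atol=1e-12)

    def test_deterministic_given_seed(self, small_dataset):
        _, data = small_dataset
        a = v.fit_lasso_gc(data, seed=9)
        b = v.fit_lasso_gc(data, seed=9)
        np.testing.assert_array_equal(a.b_hat, b.b_hat)
        np.testing.assert_array_equal(a.t_scores, b.t_scores)

    def test_voxel_permutation_equivariance(self, small_dataset):
        _, data = small_dataset
        est = v.fit_lasso_gc(data, seed=5)
        perm_x = np.array([2, 0, 1])        # permute X voxels only
        permuted = v.PairedRoiDataset(data.x_series[perm_x], data.y_series)
        est_p = v.fit_lasso_gc(permuted, seed=5)
        full = np.r_[perm_x, np.arange(3, 7)]
        np.testing.assert_allclose(est_p.b_hat, est.b_hat[np.ix_(full, full)], atol=1e-8)

    def test_true_chain_links_recovered_and_no_split_matches_modes(self):
        data = v.iterate_model(chain_model(), T=200, seed=77)
        est = v.fit_lasso_gc(data, seed=8, split="none")
        # y←x is entry (1,0); z←y is (2,1)
        assert est.selected[1, 0] and est.p_values[1, 0] < 0.01
        assert est.selected[2, 1] and est.p_values[2, 1] < 0.01


class TestFitPairwiseGc:
    def test_two_voxel_dataset_equals_full_var_fit(self):
        B = np.array([[0.4, 0.3], [-0.2, 0.5]])
        model = v.MvarModel(coeffs=[B], partition=(1, 1), innovation_sd=0.1)
        data = v.iterate_model(model, T=400, seed=6)
        est = v.fit_pairwise_gc(data)
        design, responses, *_ = lagged_arrays(data, 1)
        for i in range(2):
            b_or = np.linalg.lstsq(design, responses[:, i], rcond=None)[0]
            # cross coefficient matches the bivariate (= full, here) model
            np.testing.assert_allclose(est.b_hat[i, 1 - i], b_or[1 - i], atol=1e-10)

    def test_type_one_error_calibration_independent_voxels(self):
        # independent voxels: uncorrected p<0.05 rate for cross terms ≈ 5%
        null = v.MvarModel(coeffs=[np.zeros((8, 8))], partition=(4, 4), innovation_sd=0.1)
        rates = []
        for s in range(30):
            data = v.iterate_model(null, T=300, seed=900 + s)
            est = v.fit_pairwise_gc(data)
            off = ~np.eye(8, dtype=bool)
            rates.append((est.p_values[off] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_all_entries_estimated(self, small_dataset):
        _, data = small_dataset
        est = v.fit_pairwise_gc(data)
        assert est.selected.all()
        assert np.isfinite(est.t_scores).all()


class TestFitAveragedGc:
    def test_single_voxel_rois_equal_pairwise(self):
        B = np.array([[0.4, 0.3], [-0.2, 0.5]])
        model = v.MvarModel(coeffs=[B], partition=(1, 1), innovation_sd=0.1)
        data = v.iterate_model(model, T=300, seed=13)
        avg = v.fit_averaged_gc(data)
        pw = v.fit_pairwise_gc(data)
        assert avg.t_yx == pytest.approx(pw.t_scores[0, 1])
        assert avg.t_xy == pytest.approx(pw.t_scores[1, 0])

    def test_null_calibration(self):
        # X independent of pure-noise Y: |t_yx| exceeds the 5% critical value ≈ 5%
        null = v.MvarModel(coeffs=[np.zeros((6, 6))], partition=(3, 3), innovation_sd=0.1)
        n_obs = 199  # T − order pooled observations
        crit = stats.t.ppf(0.975, n_obs - 2)
        hits = sum(
            abs(v.fit_averaged_gc(v.iterate_model(null, T=200, seed=1500 + s)).t_yx) > crit
            for s in range(100)
        )
        assert hits / 100 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 100)


class TestResidualCorrelation:
    def test_shape_symmetry_unit_diagonal(self, small_dataset):
        _, data = small_dataset
        est = v.fit_lasso_gc(data, seed=2)
        corr = v.residual_correlation(data, est)
        assert corr.shape == (7, 7)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_well_specified_fit_has_low_offdiagonal(self, small_dataset):
        _, data = small_dataset
        est = v.fit_lasso_gc(data, seed=2, split="none")
        corr = v.residual_correlation(data, est)
        off = np.abs(corr[~np.eye(7, dtype=bool)])
        assert np.median(off) < 0.2
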