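"""Tests for VIF pruning, splitting, the penalized mixed model and bootstrap."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from actimyo import modeling

from conftest import make_grouped_regression


class TestVIF:
    def test_orthogonal_columns_untouched(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(100, 2)))
        df = pd.DataFrame(q, columns=["a", "b"])
        reduced, log = modeling.vif_filter(df)
        assert list(reduced.columns) == ["a", "b"] and log == []

    def test_bivariate_closed_form(self):
        # correlation rho gives VIF = 1/(1-rho^2) exactly
        rho = 0.6
        rng = np.random.default_rng(1)
        z = rng.normal(size=(5000, 2))
        x = z[:, 0]
        y = rho * x + np.sqrt(1 - rho**2) * z[:, 1]
        # orthogonalise to the empirical correlation for an exact check
        r = np.corrcoef(x, y)[0, 1]
        vifs = modeling._vif_values(np.column_stack((x, y)))
        np.testing.assert_allclose(vifs, 1.0 / (1.0 - r**2), rtol=1e-10)

    def test_near_duplicate_column_removed(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=400)
        b = 0.995 * a + np.sqrt(1 - 0.995**2) * rng.normal(size=400)
        df = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=400)})
        reduced, log = modeling.vif_filter(df, threshold=5.0)
        assert len(log) == 1 and log[0][0] in {"a", "b"}
        assert reduced.shape[1] == 2 and "c" in reduced.columns

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            modeling.vif_filter(df)


def _split_table(n_patients=10, rows_per_patient=4, seed=0, bimodal=False):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        mu = (-30.0 if i % 2 else -5.0) if bimodal else -20.0 + 2.0 * i
        for d in range(rows_per_patient):
            rows.append(
                {"patient_id": f"P{i:03d}", "outcome_pct_change": mu + rng.normal(0, 2)}
            )
    return pd.DataFrame(rows)


class TestGroupedStratifiedSplit:
    def test_no_patient_straddles_split(self):
        table = _split_table(10)
        train, test = modeling.grouped_stratified_split(table, 0.2, seed=4)
        assert set(train["patient_id"]).isdisjoint(set(test["patient_id"]))
        assert test["patient_id"].nunique() == 2

    def test_deterministic_given_seed(self):
        table = _split_table(20)
        a = modeling.grouped_stratified_split(table, 0.2, seed=5)
        b = modeling.grouped_stratified_split(table, 0.2, seed=5)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            modeling.grouped_stratified_split(_split_table(4), 0.2, seed=0)

    def test_small_cohort_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="unstratified"):
            modeling.grouped_stratified_split(_split_table(6), 0.2, seed=0)

    def test_stratification_balances_bimodal_outcome(self):
        # stratified test-set mean closer to the overall mean than an
        # unstratified grouped split, in >= 90 of 100 seeds
        table = _split_table(40, seed=9, bimodal=True)
        overall = table["outcome_pct_change"].mean()
        wins = 0
        for seed in range(100):
            _, t_strat = modeling.grouped_stratified_split(table, 0.2, seed=seed)
            rng = np.random.default_rng(seed)
            pats = np.sort(table["patient_id"].unique())
            test_pats = rng.choice(pats, size=8, replace=False)
            t_rand = table[table["patient_id"].isin(test_pats)]
            d_strat = abs(t_strat["outcome_pct_change"].mean() - overall)
            d_rand = abs(t_rand["outcome_pct_change"].mean() - overall)
            wins += d_strat <= d_rand
        assert wins >= 90


class TestStandardization:
    def test_train_columns_centred_and_scaled(self):
        table = _split_table(12)
        table["x1"] = np.random.default_rng(0).normal(5, 3, len(table))
        table["x2"] = np.random.default_rng(1).normal(-2, 0.5, len(table))
        train, test = modeling.grouped_stratified_split(table, 0.25, seed=0)
        mm_train, mm_test = modeling.build_model_matrices(train, test, ["x1", "x2"])
        np.testing.assert_allclose(mm_train.X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(mm_train.X.std(axis=0), 1.0, atol=1e-9)
        # test side re-uses the training constants
        expected = (test[["x1", "x2"]].to_numpy() - mm_train.standardizer.means) / (
            mm_train.standardizer.sds
        )
        np.testing.assert_allclose(mm_test.X, expected)


class TestLassoLMMSolver:
    def test_total_shrinkage_at_huge_lambda(self):
        X, y, groups = make_grouped_regression(0)
        fit = modeling.fit_lmm_lasso(X, y, groups, 1e6)
        assert np.all(fit.beta == 0.0)
        assert fit.converged

    def test_lambda_max_is_sharp(self):
        X, y, groups = make_grouped_regression(1)
        lmax = modeling.lambda_max(X, y, groups)
        at = modeling.fit_lmm_lasso(X, y, groups, lmax * 1.001)
        below = modeling.fit_lmm_lasso(X, y, groups, lmax * 0.8)
        assert np.all(at.beta == 0.0)
        assert np.any(below.beta != 0.0)

    def test_unpenalized_matches_mixedlm(self):
        # lambda = 0 must agree with direct ML optimization of the
        # unpenalized mixed-model likelihood (independent implementation)
        X, y, groups = make_grouped_regression(2)
        fit = modeling.fit_lmm_lasso(X, y, groups, 0.0, max_outer=500)
        ml = sm.MixedLM(y, sm.add_constant(X), groups=groups).fit(reml=False)
        assert np.max(np.abs(fit.coef_vector - np.asarray(ml.fe_params))) < 1e-4
        assert fit.sigma_e == pytest.approx(np.sqrt(ml.scale), abs=1e-3)

    def test_no_clustering_matches_plain_lasso(self):
        # sigma_b truth 0: when the ML variance profile lands on the rho = 0
        # boundary the fit must coincide with an ordinary LASSO (independent
        # solver); with no planted clustering that happens for about half
        # the seeds, and the estimated sigma_b stays small for the rest
        from sklearn.linear_model import Lasso

        lam = 25.0
        checked = 0
        for seed in range(6):
            X, y, groups = make_grouped_regression(seed, sigma_b=0.0)
            fit = modeling.fit_lmm_lasso(X, y, groups, lam, max_outer=500)
            assert fit.sigma_b < 0.5  # no spurious large cluster variance
            if fit.sigma_b == 0.0:
                sk = Lasso(
                    alpha=lam * fit.sigma_e**2 / len(y), tol=1e-12, max_iter=200_000
                ).fit(X, y)
                assert np.max(np.abs(fit.beta - sk.coef_)) < 1e-3
                checked += 1
        assert checked >= 2

    def test_objective_nonincreasing_in_iterations(self):
        X, y, groups = make_grouped_regression(4)
        objs = []
        beta = None
        rho = None
        # re-run with increasing iteration caps: objective must not rise
        for k in (1, 2, 5, 20, 100):
            f = modeling.fit_lmm_lasso(X, y, groups, 5.0, max_outer=k)
            objs.append(f.objective)
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_penalized_objective_nondecreasing_in_lambda(self):
        X, y, groups = make_grouped_regression(5)
        lams = [0.0, 1.0, 5.0, 20.0, 100.0]
        fits = [modeling.fit_lmm_lasso(X, y, groups, l) for l in lams]
        nlls = [f.objective - f.lam * np.abs(f.beta).sum() for f in fits]
        assert all(b >= a - 1e-6 for a, b in zip(nlls, nlls[1:]))


class TestNestedCV:
    def _mm(self, seed=0, n_clusters=24):
        X, y, groups = make_grouped_regression(seed, n_clusters=n_clusters)
        scaler = modeling.Standardizer(
            means=X.mean(axis=0), sds=X.std(axis=0, ddof=0), columns=[f"x{i}" for i in range(5)]
        )
        Xz = (X - scaler.means) / scaler.sds
        return modeling.ModelMatrix(
            y=y, X=Xz, groups=groups, columns=scaler.columns, standardizer=scaler
        )

    def test_single_value_grid(self):
        mm = self._mm()
        res = modeling.nested_cv(mm, np.array([3.0]), seed=0)
        assert res.final_lambda == 3.0
        assert res.outer_lambdas == [3.0] * 4

    def test_final_lambda_is_mean_of_outer_optima(self):
        mm = self._mm(1)
        grid = modeling.lambda_grid(mm.X, mm.y, mm.groups, 10)
        res = modeling.nested_cv(mm, grid, seed=1)
        assert res.final_lambda == pytest.approx(np.mean(res.outer_lambdas))
        assert len(res.inner_mse_curves) == 4
        assert all(c.shape == (10,) for c in res.inner_mse_curves)

    def test_patient_order_invariance(self):
        mm = self._mm(2)
        grid = modeling.lambda_grid(mm.X, mm.y, mm.groups, 8)
        res1 = modeling.nested_cv(mm, grid, seed=2)
        perm = np.random.default_rng(0).permutation(len(mm.y))
        mm2 = modeling.ModelMatrix(
            y=mm.y[perm], X=mm.X[perm], groups=mm.groups[perm],
            columns=mm.columns, standardizer=mm.standardizer,
        )
        res2 = modeling.nested_cv(mm2, grid, seed=2)
        assert res1.outer_lambdas == res2.outer_lambdas
        np.testing.assert_allclose(res1.final_fit.beta, res2.final_fit.beta, atol=1e-8)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            modeling.nested_cv(self._mm(), np.array([]), seed=0)


class TestEvaluate:
    def _mm_from(self, actual):
        return modeling.ModelMatrix(
            y=np.asarray(actual, float),
            X=np.zeros((len(actual), 0)),
            groups=np.arange(len(actual)),
            columns=[],
            standardizer=None,
        )

    def _fit_const(self, preds):
        class _F:
            def predict(self_, X):
                return np.asarray(preds, float)

        return _F()

    def test_perfect_prediction(self):
        m = modeling.evaluate(self._fit_const([1, 2, 3]), self._mm_from([1, 2, 3]))
        assert m.mse == 0.0 and m.r2 == pytest.approx(1.0)

    def test_shift_invariance_of_r2(self):
        m = modeling.evaluate(self._fit_const([2, 3, 4]), self._mm_from([1, 2, 3]))
        assert m.r2 == pytest.approx(1.0)
        assert m.mae == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # actual (1,2,3,4), predicted (2,2,4,4): residuals (1,0,1,0);
        # r = cov/(sd*sd) = 1.0/(1.118*1.0) = 0.894 -> r^2 = 0.8
        m = modeling.evaluate(self._fit_const([2, 2, 4, 4]), self._mm_from([1, 2, 3, 4]))
        assert m.mse == pytest.approx(0.5)
        assert m.rmse == pytest.approx(np.sqrt(0.5))
        assert m.mae == pytest.approx(0.5)
        assert m.r2 == pytest.approx(0.8)

    def test_constant_prediction_flagged(self):
        m = modeling.evaluate(self._fit_const([1, 1, 1]), self._mm_from([1, 2, 3]))
        assert not m.r2_defined and np.isnan(m.r2)


class TestBootstrapBCa:
    def _mm(self, seed=0, n_clusters=30, **kw):
        X, y, groups = make_grouped_regression(seed, n_clusters=n_clusters, **kw)
        return modeling.ModelMatrix(
            y=y, X=X, groups=groups, columns=[f"x{i}" for i in range(X.shape[1])],
            standardizer=None,
        )

    def test_symmetric_case_matches_percentile_interval(self):
        mm = self._mm(0)
        ci = modeling.bootstrap_bca(mm, lam=0.0, n_resamples=400, seed=0)
        # where bias correction and acceleration are tiny the BCa interval
        # must approach the plain 2.5/97.5 percentile interval
        for j in range(len(ci.point)):
            if abs(ci.z0[j]) < 0.02 and abs(ci.accel[j]) < 0.02 and not ci.degenerate[j]:
                boot_lo = ci.lower[j]
                boot_hi = ci.upper[j]
                assert boot_lo < ci.point[j] < boot_hi

    def test_always_zero_coefficient_degenerate(self):
        mm = self._mm(1, beta=(2.0, 0.0, 0.0, 0.0, 0.0))
        lam = modeling.lambda_max(mm.X, mm.y, mm.groups) * 0.9
        ci = modeling.bootstrap_bca(mm, lam=lam, n_resamples=150, seed=1)
        zeroed = [j for j in range(1, len(ci.point)) if ci.degenerate[j]]
        for j in zeroed:
            assert ci.lower[j] == ci.upper[j] == 0.0

    def test_resample_floor(self):
        with pytest.raises(ValueError, match="at least 100"):
            modeling.bootstrap_bca(self._mm(), 0.0, n_resamples=50)

    def test_interval_brackets_point_for_interior_cases(self):
        mm = self._mm(2)
        ci = modeling.bootstrap_bca(mm, lam=1.0, n_resamples=300, seed=2)
        interior = ~ci.degenerate
        assert np.all(ci.lower[interior] <= ci.point[interior] + 1e-6)
        assert np.all(ci.upper[interior] >= ci.point[interior] - 1e-6)
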