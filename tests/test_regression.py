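import numpy as np
import pandas as pd
import pytest

from conftest import make_planted_dataset
from matodd import regression as rg


class TestAssemble:
    def test_shapes_and_alignment(self):
        X = pd.DataFrame(np.eye(2), columns=["f0", "f1"], index=["a", "b"])
        y = pd.Series([1.0, 2.0], index=["b", "a"])
        t = pd.Series(["T", "T"], index=["a", "b"])
        ds = rg.assemble_dataset(X, y, t)
        assert ds.X.shape == (2, 2)
        assert ds.y.loc["a"] == 2.0  # aligned by label, not position

    def test_unmatched_condition_reported(self):
        X = pd.DataFrame(np.eye(2), columns=["f0", "f1"], index=["a", "b"])
        y = pd.Series([1.0], index=["a"])
        t = pd.Series(["T"], index=["a"])
        with pytest.raises(ValueError, match="unmatched"):
            rg.assemble_dataset(X, y, t)

    def test_zero_distance_row_allowed(self):
        X = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], columns=["f0", "f1"],
                         index=["a", "b"])
        y = pd.Series([0.0, 1.0], index=["a", "b"])
        t = pd.Series(["T", "T"], index=["a", "b"])
        ds = rg.assemble_dataset(X, y, t)
        assert (ds.X.loc["a"] == 0).all()


class TestSplit:
    def _dataset(self, n_tasks=6, per_task=5, seed=0):
        n = n_tasks * per_task
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=n))
        t = pd.Series(np.repeat([f"T{i}" for i in range(n_tasks)], per_task))
        X.index = y.index = t.index = [f"c{i}" for i in range(n)]
        return rg.assemble_dataset(X, y, t)

    def test_30_rows_split_24_6_one_per_task(self):
        ds = self._dataset()
        train, test = rg.split_train_test(ds, seed=1)
        assert len(train) == 24 and len(test) == 6
        assert sorted(test.task.unique()) == sorted(ds.task.unique())
        assert test.task.value_counts().max() == 1

    def test_same_seed_same_split(self):
        ds = self._dataset()
        a = rg.split_train_test(ds, seed=7)
        b = rg.split_train_test(ds, seed=7)
        assert list(a[1].X.index) == list(b[1].X.index)

    def test_test_frequency_near_twenty_percent(self):
        ds = self._dataset()
        counts = pd.Series(0, index=ds.X.index)
        n_seeds = 600
        for s in range(n_seeds):
            _, test = rg.split_train_test(ds, seed=s)
            counts[test.X.index] += 1
        freq = counts / n_seeds
        assert abs(freq.mean() - 0.2) < 0.01
        # binomial SE at p=0.2, n=600 is ~1.6%; allow 4 SwithE per row
        assert (np.abs(freq - 0.2) < 0.07).all()


class TestOls:
    def test_exact_linear_zero_residuals(self):
        ds, _ = make_planted_dataset(n=30, p=3, planted=(0, 1, 2), snr=1e9, seed=1)
        fit = rg.fit_ols(ds)
        resid = ds.y.to_numpy() - fit.predict(ds.X)
        assert np.max(np.abs(resid)) < 1e-6

    def test_agrees_with_pseudoinverse_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            n, p = 40, 6
            X = pd.DataFrame(rng.normal(size=(n, p)),
                             columns=[f"f{j}" for j in range(p)])
            y = pd.Series(rng.normal(size=n))
            t = pd.Series(["T"] * n)
            X.index = y.index = t.index = [f"c{i}" for i in range(n)]
            ds = rg.assemble_dataset(X, y, t)
            fit = rg.fit_ols(ds)
            # oracle: normal equations via pseudo-inverse on standardized X
            Xs = (X - X.mean()) / X.std(ddof=0)
            A = np.column_stack([np.ones(n), Xs.to_numpy()])
            beta = np.linalg.pinv(A) @ y.to_numpy()
            assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
            assert np.allclose(fit.coef.to_numpy(), beta[1:], atol=1e-8)

    def test_rank_deficient_names_columns(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["u", "v"])
        X["w"] = X["u"] + X["v"]  # exactly collinear
        y = pd.Series(rng.normal(size=20))
        t = pd.Series(["T"] * 20)
        X.index = y.index = t.index = [f"c{i}" for i in range(20)]
        ds = rg.assemble_dataset(X, y, t)
        with pytest.raises(ValueError, match="collinear"):
            rg.fit_ols(ds)

    def test_nested_feature_sets_never_worsen_in_sample_fit(self):
        ds, _ = make_planted_dataset(n=50, p=10, planted=(0, 3), snr=2, seed=2)
        small = rg.RegressionDataset(ds.X.iloc[:, :4], ds.y, ds.task)
        sse = {}
        for name, d in [("small", small), ("full", ds)]:
            fit = rg.fit_ols(d)
            sse[name] = float(np.sum((d.y.to_numpy() - fit.predict(d.X)) ** 2))
        assert sse["full"] <= sse["small"] + 1e-10


class TestFixedSupportLasso:
    def test_returns_exactly_k_nonzeros(self):
        ds, planted = make_planted_dataset(seed=5)
        fit = rg.fit_lasso_fixed_support(ds, k=18, seed=0)
        assert len(fit.support) == 18

    def test_planted_features_recovered(self):
        ds, planted = make_planted_dataset(seed=6)
        fit = rg.fit_lasso_fixed_support(ds, k=18, seed=0)
        assert set(planted) <= set(fit.support)

    def test_recovery_rate_across_replicates(self):
        """Planted supports recovered in >= 90% of replicates at SNR 5."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            ds, planted = make_planted_dataset(n=75, p=96, snr=5.0, seed=1000 + rep)
            fit = rg.fit_lasso_fixed_support(ds, k=18, seed=rep)
            hits += set(planted) <= set(fit.support)
        assert hits / n_rep >= 0.90

    def test_support_target_must_be_feasible(self):
        ds, _ = make_planted_dataset(n=30, p=5, planted=(0,), seed=0)
        with pytest.raises(ValueError):
            rg.fit_lasso_fixed_support(ds, k=5)

    def test_standardization_uses_train_only(self):
        ds, _ = make_planted_dataset(seed=8)
        train, test = rg.split_train_test(ds, seed=3)
        fit = rg.fit_lasso_fixed_support(train, k=18, seed=0)
        # the fit's centering/scaling must equal the train split's statistics
        assert np.allclose(fit.x_mean.to_numpy(), train.X.mean().to_numpy())
        assert np.allclose(
            fit.x_sd.to_numpy(), train.X.std(ddof=0).to_numpy()
        )
        assert not np.allclose(fit.x_mean.to_numpy(), ds.X.mean().to_numpy())

    def test_lambda_modes_both_reach_target_support(self):
        ds, _ = make_planted_dataset(seed=9)
        for mode in ("cv_min", "first"):
            fit = rg.fit_lasso_fixed_support(ds, k=18, seed=0, lambda_mode=mode)
            assert len(fit.support) == 18


class TestResampleEvaluate:
    def test_noise_free_planted_model_r2_near_one(self):
        ds, _ = make_planted_dataset(n=60, p=8, planted=(0, 2), snr=1e6, seed=3)
        res = rg.resample_evaluate(ds, "color_stats", n_resamples=40, seed=0)
        assert res.median_r2 > 0.999

    def test_independent_response_r2_nonpositive(self):
        rng = np.random.default_rng(12)
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=n))
        t = pd.Series(np.repeat([f"T{i}" for i in range(6)], 10))
        X.index = y.index = t.index = [f"c{i}" for i in range(n)]
        ds = rg.assemble_dataset(X, y, t)
        res = rg.resample_evaluate(ds, "color_means", n_resamples=60, seed=0)
        assert res.median_r2 <= 0.05

    def test_fixed_seed_fixes_distributions(self):
        ds, _ = make_planted_dataset(n=60, p=8, planted=(0, 2), seed=4)
        a = rg.resample_evaluate(ds, "color_stats", n_resamples=15, seed=5)
        b = rg.resample_evaluate(ds, "color_stats", n_resamples=15, seed=5)
        assert np.array_equal(a.mse_distribution, b.mse_distribution)
        assert np.array_equal(a.r2_distribution, b.r2_distribution)

    def test_per_task_cis_bracket_mean(self):
        ds, _ = make_planted_dataset(n=60, p=8, planted=(0, 2), snr=3, seed=4)
        res = rg.resample_evaluate(ds, "color_stats", n_resamples=60, seed=0)
        for _, row in res.per_task_mse.iterrows():
            assert row["ci_lo"] <= row["mse"] + 1e-12
            assert row["mse"] <= row["ci_hi"] + 1e-12
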