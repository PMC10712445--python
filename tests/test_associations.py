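"""Sparse PLS, tuning/stability, confirmatory OLS, stepwise AIC."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from efficacy_hgf.associations import (confirmatory_ols, spls_fit,
                                       spls_predict, stepwise_backward_aic,
                                       tune_spls)
from efficacy_hgf.cohort import planted_association_data


@pytest.fixture(scope="module")
def correlated_data():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((30, 5))
    Y = X @ rng.standard_normal((5, 4)) + 0.5 * rng.standard_normal((30, 4))
    return X, Y


class TestSplsFit:
    def test_dense_matches_reference_pls(self, correlated_data):
        X, Y = correlated_data
        ours = spls_fit(X, Y, n_components=2)
        ref = PLSRegression(n_components=2, scale=True).fit(X, Y)
        for h in range(2):
            r = np.corrcoef(ours.x_scores[:, h], ref.x_scores_[:, h])[0, 1]
            assert abs(r) > 0.9999

    def test_univariate_selects_max_covariance_column(self):
        rng = np.random.default_rng(3)
        for rep in range(20):
            X = rng.standard_normal((25, 7))
            y = rng.standard_normal(25)
            fit = spls_fit(X, y, n_components=1, keep_x=1)
            Xs = (X - X.mean(0)) / X.std(0, ddof=1)
            ys = (y - y.mean()) / y.std(ddof=1)
            brute = int(np.argmax(np.abs(Xs.T @ ys)))
            assert fit.selected_X == [brute]

    def test_score_covariance_non_increasing(self, correlated_data):
        X, Y = correlated_data
        fit = spls_fit(X, Y, n_components=3)
        covs = [abs(np.cov(fit.x_scores[:, h], fit.y_scores[:, h])[0, 1])
                for h in range(3)]
        assert covs[0] >= covs[1] >= covs[2]

    def test_variance_explained_bounds_and_null(self):
        rng = np.random.default_rng(9)
        # permutation null: observed VE rarely beats the permutation tail
        hits = 0
        n_datasets = 30
        for i in range(n_datasets):
            X = rng.standard_normal((21, 6))
            Y = rng.standard_normal((21, 8))
            obs = spls_fit(X, Y, 1, keep_x=2, keep_y=3).variance_explained_Y
            assert 0.0 <= obs <= 1.0
            perm = []
            for _ in range(40):
                Yp = Y[rng.permutation(21)]
                perm.append(spls_fit(X, Yp, 1, keep_x=2,
                                     keep_y=3).variance_explained_Y)
            hits += obs > np.quantile(perm, 0.95)
        assert hits / n_datasets < 0.25

    def test_keep_bounds_rejected(self, correlated_data):
        X, Y = correlated_data
        with pytest.raises(ValueError):
            spls_fit(X, Y, 1, keep_x=99)
        with pytest.raises(ValueError):
            spls_fit(X, Y, n_components=30)

    def test_prediction_reduces_error(self, correlated_data):
        X, Y = correlated_data
        fit = spls_fit(X[:20], Y[:20], n_components=2)
        pred = spls_predict(fit, X[20:])
        mse_model = np.mean((Y[20:] - pred) ** 2)
        mse_mean = np.mean((Y[20:] - Y[:20].mean(0)) ** 2)
        assert mse_model < mse_mean


class TestTuneSpls:
    def test_planted_structure_recovered(self):
        X, Y = planted_association_data(seed=0)
        res = tune_spls(X, Y, components_grid=(1, 2), keep_x_grid=(2,),
                        keep_y_grid=(3,), folds=4, repeats=50, seed=0)
        assert res["stable_X"] == [0, 1]
        assert res["stable_Y"] == [0, 1, 2]
        assert res["n_refits"] == 50 * 4

    def test_null_loading_selects_nothing(self):
        rng = np.random.default_rng(123)
        X = rng.standard_normal((21, 6))
        Y = rng.standard_normal((21, 8))
        res = tune_spls(X, Y, components_grid=(1, 2), keep_x_grid=(2,),
                        keep_y_grid=(3,), folds=4, repeats=50, seed=1)
        assert res["n_components"] == 0
        assert res["stable_X"] == [] and res["stable_Y"] == []

    def test_deterministic_given_seed(self):
        X, Y = planted_association_data(seed=5)
        a = tune_spls(X, Y, components_grid=(1,), keep_x_grid=(2,),
                      keep_y_grid=(3,), repeats=10, seed=7)
        b = tune_spls(X, Y, components_grid=(1,), keep_x_grid=(2,),
                      keep_y_grid=(3,), repeats=10, seed=7)
        assert a["stability_freq_X"] == b["stability_freq_X"]
        assert a["cv_mse"] == b["cv_mse"]

    def test_too_small_to_split(self):
        with pytest.raises(ValueError):
            tune_spls(np.zeros((5, 2)), np.zeros((5, 2)), folds=4, repeats=1)


class TestConfirmatoryOLS:
    def test_exact_linear_fit(self):
        x = np.linspace(-1, 1, 30)
        tab = confirmatory_ols(2.0 * x, x)
        assert tab.loc["0", "estimate"] == pytest.approx(2.0, abs=1e-10)
        assert tab.loc["0", "p"] < 1e-20

    def test_orthogonal_predictor_gets_zero(self):
        x = np.concatenate([np.ones(10), -np.ones(10)])
        y = np.tile([1.0, -1.0], 10)  # orthogonal to x by construction
        tab = confirmatory_ols(y, x)
        assert tab.loc["0", "estimate"] == pytest.approx(0.0, abs=1e-12)

    def test_slope_coverage(self):
        rng = np.random.default_rng(2024)
        covered = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.standard_normal(40)
            y = 1.5 * x + rng.standard_normal(40)
            tab = confirmatory_ols(y, x)
            covered += abs(tab.loc["0", "estimate"] - 1.5) < \
                2 * tab.loc["0", "se"]
        assert covered / n_sim >= 0.92

    def test_collinearity_rejected(self):
        x = np.linspace(0, 1, 20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError):
            confirmatory_ols(x, X)


class TestStepwise:
    def test_final_aic_never_exceeds_full(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.standard_normal((40, 5))
            y = rng.standard_normal(40)
            res = stepwise_backward_aic(y, X)
            assert res.final_aic <= res.full_aic + 1e-9
            # the path is monotone decreasing in AIC
            aics = [a for _, a in res.path]
            assert all(a > b for a, b in zip(aics, aics[1:])) or len(aics) < 2

    def test_null_predictors_mostly_eliminated(self):
        # under pure noise each predictor survives AIC elimination with
        # probability ~P(chi2_1 > 2) ~ 0.157, so the empty model is the
        # modal outcome (~0.84^5 ~ 42%) and retention is sparse
        rng = np.random.default_rng(1)
        n_retained = []
        for _ in range(100):
            X = rng.standard_normal((200, 5))
            y = rng.standard_normal(200)
            n_retained.append(len(stepwise_backward_aic(y, X).retained))
        counts = np.bincount(n_retained, minlength=6)
        assert counts[0] + counts[1] > 60  # mass concentrated on {0, 1}
        assert np.mean(n_retained) < 1.5

    def test_planted_predictor_retained(self):
        rng = np.random.default_rng(2)
        kept = 0
        for _ in range(100):
            X = rng.standard_normal((60, 5))
            y = 1.0 * X[:, 2] + rng.standard_normal(60)
            res = stepwise_backward_aic(y, X)
            kept += "2" in res.retained
        assert kept >= 95

    def test_named_columns_flow_through(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((50, 3)),
                         columns=["a", "b", "c"])
        y = 2 * X["b"] + 0.1 * rng.standard_normal(50)
        res = stepwise_backward_aic(y, X)
        assert "b" in res.retained
        assert "b" in res.table.index
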