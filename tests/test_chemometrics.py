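"""Model-development engine: filters, splitting, PLS, SVM, metrics,
validation diagnostics and exploration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fabqsar.chemometrics import (SvmConfig, hca_complete_linkage,
                                  kennard_stone_split, mcc, metrics,
                                  pca_explore, pls_fit, prediction_interval,
                                  r_squared, rmse, sensitivity_specificity,
                                  svm_train_grid, variance_filter,
                                  vwsp_reduce)
from fabqsar.chemometrics.pls import cv_rmse_pls
from fabqsar.chemometrics.scaling import autoscale_full
from fabqsar.errors import (DegenerateResponse, EmptyInput, TooFew,
                            TooFewSamples)


def frame(arr, prefix="d"):
    arr = np.asarray(arr, float)
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestVarianceFilter:
    def test_constant_column_removed(self, rng):
        x = frame(np.column_stack([rng.normal(size=10), np.full(10, 3.0)]))
        kept, removed = variance_filter(x)
        assert removed == ["d1"]

    def test_sd_exactly_at_threshold_kept(self):
        # column engineered to have sd exactly 0.01 with threshold 0.01
        col = np.array([-0.01, 0.01, -0.01, 0.01])  # sd = 0.011547 (ddof=1)
        sd = np.std(col, ddof=1)
        x = frame(col[:, None] / sd * 0.01)
        kept, removed = variance_filter(x, sd_threshold=0.01)
        assert removed == []

    def test_hand_counted_survivors(self, rng):
        x = np.column_stack([
            rng.normal(size=5),            # survives
            np.full(5, 1.0),               # constant
            rng.normal(size=5) * 1e-6,     # tiny spread
            rng.normal(size=5),            # survives
        ])
        kept, removed = variance_filter(frame(x))
        per_col_sd = np.std(x, ddof=1, axis=0)
        expected_removed = [f"d{j}" for j in range(4)
                            if per_col_sd[j] < 1e-4]
        assert removed == expected_removed


def bruteforce_kennard_stone(x: np.ndarray, n_cal: int) -> list[int]:
    """Independent max-min selection with explicit loops."""
    n = len(x)
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    best, pair = -1.0, (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best:
                best, pair = d[i, j], (i, j)
    chosen = list(pair)
    while len(chosen) < n_cal:
        cand_best, cand = -1.0, None
        for k in range(n):
            if k in chosen:
                continue
            mind = min(d[k, c] for c in chosen)
            if mind > cand_best:
                cand_best, cand = mind, k
        chosen.append(cand)
    return chosen


class TestKennardStone:
    def test_one_dimensional_example(self):
        x = frame(np.array([[0.0], [1.0], [10.0], [5.0], [9.0]]))
        split = kennard_stone_split(x, calibration_fraction=0.6)
        assert set(split.calibration_ids) == {"s0", "s2", "s3"}

    def test_calibration_fraction_is_80_percent(self, rng):
        x = frame(rng.normal(size=(41, 4)))
        split = kennard_stone_split(x)
        assert len(split.calibration_ids) == round(0.8 * 41)
        assert set(split.calibration_ids) | set(split.test_ids) == \
            set(x.index)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(9, 3))
        scaled = autoscale_full(frame(x)).to_numpy()
        split = kennard_stone_split(frame(x), calibration_fraction=0.6)
        expected = bruteforce_kennard_stone(scaled, round(0.6 * 9))
        assert split.calibration_ids == [f"s{k}" for k in expected]

    def test_duplicate_rows_deterministic(self):
        x = frame(np.array([[0.0], [0.0], [5.0], [5.0], [9.0], [2.0]]))
        a = kennard_stone_split(x, 0.5)
        b = kennard_stone_split(x, 0.5)
        assert a.calibration_ids == b.calibration_ids

    def test_stratified_keeps_label_ratio(self, rng):
        x = frame(rng.normal(size=(30, 3)))
        labels = pd.Series(["a"] * 20 + ["b"] * 10, index=x.index)
        split = kennard_stone_split(x, 0.8, stratify_by=labels)
        cal_labels = labels.loc[split.calibration_ids]
        assert (cal_labels == "a").sum() == 16
        assert (cal_labels == "b").sum() == 8

    def test_too_few_samples(self):
        with pytest.raises(TooFewSamples):
            kennard_stone_split(frame(np.zeros((3, 2))))


class TestVwsp:
    def test_identical_columns_reduced(self, rng):
        col = rng.normal(size=12)
        x = frame(np.column_stack([col, col, rng.normal(size=12)]))
        retained = vwsp_reduce(x, 0.95)
        assert len([c for c in retained if c in ("d0", "d1")]) == 1

    def test_threshold_one_is_noop(self, rng):
        x = frame(rng.normal(size=(10, 6)))
        assert sorted(vwsp_reduce(x, 1.0)) == sorted(x.columns)

    def test_no_retained_pair_above_threshold(self, rng):
        base = rng.normal(size=(20, 3))
        cols = [base[:, 0], base[:, 0] + 0.05 * rng.normal(size=20),
                base[:, 1], base[:, 1] * -1 + 0.05 * rng.normal(size=20),
                base[:, 2], rng.normal(size=20)]
        x = frame(np.column_stack(cols))
        retained = vwsp_reduce(x, 0.9)
        corr = x[retained].corr().to_numpy()
        off = corr[~np.eye(len(retained), dtype=bool)]
        assert np.all(np.abs(off) <= 0.9 + 1e-12)


class TestPls:
    def test_single_informative_column_one_component(self, rng):
        # other columns orthogonalised to the informative one, so a single
        # latent variable captures the response exactly
        x = rng.normal(size=(20, 4))
        x = x - x.mean(0)
        for j in (0, 1, 3):
            x[:, j] -= (x[:, j] @ x[:, 2]) / (x[:, 2] @ x[:, 2]) * x[:, 2]
        y = 3.0 * x[:, 2]
        model = pls_fit(x, y, 1)
        assert np.allclose(model.predict(x, 1), y, atol=1e-8)

    def test_full_rank_equals_least_squares(self, rng):
        x = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = pls_fit(x, y, 5)
        xc = np.column_stack([np.ones(20), x])
        beta = np.linalg.solve(xc.T @ xc, xc.T @ y)  # normal equations
        ols_pred = xc @ beta
        assert np.allclose(model.predict(x, 5), ols_pred, atol=1e-8)

    def test_matches_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        x = rng.normal(size=(30, 8))
        y = x[:, 0] - 2 * x[:, 3] + 0.1 * rng.normal(size=30)
        ours = pls_fit(x, y, 3).predict(x, 3)
        sk = PLSRegression(n_components=3, scale=False).fit(x, y)
        assert np.allclose(ours, sk.predict(x).ravel(), atol=1e-6)

    def test_constant_shift_moves_intercept_only(self, rng):
        x = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        m1 = pls_fit(x, y, 2)
        m2 = pls_fit(x, y + 10.0, 2)
        assert np.allclose(m1.coefficients(2), m2.coefficients(2))
        assert np.allclose(m2.predict(x, 2), m1.predict(x, 2) + 10.0)

    def test_components_capped_at_rank(self, rng):
        x = rng.normal(size=(6, 10))
        y = rng.normal(size=6)
        with pytest.warns(UserWarning):
            model = pls_fit(x, y, 10)
        assert model.n_components <= 5

    def test_cv_selects_low_error_component_count(self, rng):
        x = rng.normal(size=(40, 6))
        y = x[:, 1] + 0.01 * rng.normal(size=40)
        best_rmse, best_k = cv_rmse_pls(x, y, 5, seed=0)
        assert best_rmse < 0.05


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert rmse(y, y) == 0.0

    def test_mean_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_r2_negative_when_worse_than_mean(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.array([5.0, -4.0, 9.0])) < 0

    def test_binary_mcc_matches_textbook_formula(self):
        # confusion counts TP=4, FP=1, TN=3, FN=2
        y_true = ["p"] * 6 + ["n"] * 4
        y_pred = ["p"] * 4 + ["n"] * 2 + ["p"] * 1 + ["n"] * 3
        tp, fp, tn, fn = 4, 1, 3, 2
        expected = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert mcc(y_true, y_pred) == pytest.approx(expected)

    def test_mcc_matches_sklearn(self, rng):
        from sklearn.metrics import matthews_corrcoef

        y_true = rng.choice(["a", "b", "c"], size=60)
        y_pred = np.where(rng.random(60) < 0.7, y_true,
                          rng.choice(["a", "b", "c"], size=60))
        assert mcc(y_true, y_pred) == pytest.approx(
            matthews_corrcoef(y_true, y_pred))

    def test_sensitivity_specificity_hand_counts(self):
        y_true = ["p"] * 6 + ["n"] * 4
        y_pred = ["p"] * 4 + ["n"] * 2 + ["p"] * 1 + ["n"] * 3
        per = sensitivity_specificity(y_true, y_pred)
        assert per["p"]["sensitivity"] == pytest.approx(4 / 6)
        assert per["p"]["specificity"] == pytest.approx(3 / 4)

    def test_empty_inputs_raise(self):
        with pytest.raises(EmptyInput):
            metrics([], [], "regression")


class TestPredictionInterval:
    def test_zero_residuals(self):
        assert prediction_interval(np.zeros(10)) == 0.0

    def test_monotone_in_spread(self):
        a = prediction_interval(np.array([-1.0, 1.0, -1.0, 1.0]))
        b = prediction_interval(np.array([-2.0, 2.0, -2.0, 2.0]))
        assert b > a

    def test_matches_hand_computed_t_interval(self):
        resid = np.array([0.5, -0.3, 0.2, -0.4, 0.1])
        n = 5
        expected = stats.t.ppf(0.975, 4) * np.std(resid, ddof=1) * \
            np.sqrt(1 + 1 / n)
        assert prediction_interval(resid) == pytest.approx(expected)

    def test_too_few_residuals(self):
        with pytest.raises(TooFew):
            prediction_interval([0.1, 0.2])


class TestHca:
    def test_three_point_merge_heights(self):
        x = frame(np.array([[0.0], [1.0], [10.0]]))
        merges = hca_complete_linkage(x)
        assert merges["height"].tolist() == pytest.approx([1.0, 10.0])

    def test_duplicates_merge_at_zero(self):
        x = frame(np.array([[2.0], [2.0], [7.0]]))
        merges = hca_complete_linkage(x)
        assert merges["height"].iloc[0] == 0.0

    def test_heights_monotone(self, rng):
        x = frame(rng.normal(size=(12, 4)))
        merges = hca_complete_linkage(x)
        assert np.all(np.diff(merges["height"]) >= -1e-12)


class TestPca:
    def test_rank_one_single_component(self, rng):
        v = rng.normal(size=5)
        scores = rng.normal(size=8)
        x = frame(np.outer(scores, v))
        out = pca_explore(x)
        ev = out["explained_variance"]
        assert ev[0] > 0
        assert np.all(ev[1:] < 1e-20 * ev[0] + 1e-12)

    def test_full_rank_reconstruction(self, rng):
        x = frame(rng.normal(size=(6, 3)))
        out = pca_explore(x)
        recon = out["scores"].to_numpy() @ out["loadings"].to_numpy().T
        centred = x.to_numpy() - x.to_numpy().mean(0)
        assert np.allclose(recon, centred, atol=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(4, 3))
        out = pca_explore(frame(x))
        centred = x - x.mean(0)
        eigvals = np.sort(np.linalg.eigvalsh(centred.T @ centred / 3))[::-1]
        assert np.allclose(out["explained_variance"], eigvals, atol=1e-10)
        loadings = out["loadings"].to_numpy()
        assert np.allclose(loadings.T @ loadings, np.eye(3), atol=1e-10)


class TestSvm:
    def test_regression_grid_has_90_pairs(self):
        assert len(SvmConfig().grid()) == 90

    def test_noiseless_linear_data_fits_perfectly(self, rng):
        x = frame(rng.normal(size=(30, 4)))
        y = pd.Series(x.to_numpy() @ np.array([1.0, -2.0, 0.5, 0.0]),
                      index=x.index)
        bundle = svm_train_grid(x, y, config=SvmConfig(cv_repeats=2))
        assert bundle.metrics["r2_cal"] >= 0.999

    def test_separable_classification_mcc_one(self, rng):
        x = np.vstack([rng.normal(-3, 0.3, size=(10, 2)),
                       rng.normal(3, 0.3, size=(10, 2))])
        y = pd.Series(["neg"] * 10 + ["pos"] * 10,
                      index=[f"s{i}" for i in range(20)])
        bundle = svm_train_grid(frame(x), y, config=SvmConfig(
            mode="c_classification", cv_repeats=2))
        assert bundle.metrics["mcc_cal"] == pytest.approx(1.0)

    def test_constant_response_raises(self, rng):
        x = frame(rng.normal(size=(10, 3)))
        y = pd.Series(np.ones(10), index=x.index)
        with pytest.raises(DegenerateResponse):
            svm_train_grid(x, y, config=SvmConfig(cv_repeats=2))

    def test_model_bundle_json_round_trip(self, rng, tmp_path):
        import json

        x = frame(rng.normal(size=(20, 3)))
        y = pd.Series(x["d0"] * 2.0 + 0.01 * rng.normal(size=20),
                      index=x.index)
        bundle = svm_train_grid(x, y, config=SvmConfig(cv_repeats=2))
        path = tmp_path / "model.json"
        bundle.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["selected"] == ["d0", "d1", "d2"]
        assert payload["hyperparameters"]["C"] == bundle.c
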