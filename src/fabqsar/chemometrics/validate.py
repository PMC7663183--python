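"""Model validation diagnostics.

Y-randomisation retrains the model on permuted responses: a mean CV R²
near zero (or negative) shows the unscrambled model is not a chance
correlation. The learning curve tracks calibration/CV/test RMSE as the
calibration subset grows in Kennard–Stone selection order, using the
optimised hyperparameters of the full calibration model. The prediction
interval converts test-set residuals into a ± band via the Student-t
predictive form.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import TooFew
from .metrics import r_squared, rmse
from .scaling import Autoscaler
from .svm import ModelBundle, SvmConfig, _make_estimator, repeated_kfold_cv


def y_randomisation(calibration: pd.DataFrame, y_cal: pd.Series,
                    selected: list[str], c: float, epsilon: float | None,
                    config: SvmConfig | None = None,
                    n_repeats: int = 50, seed: int = 0) -> dict:
    """Scrambled-response control with the selected descriptors and
    chosen hyperparameters; returns per-repeat and mean CV metrics."""
    config = config or SvmConfig()
    scaler = Autoscaler.fit(calibration[selected])
    x = scaler.transform(calibration[selected]).to_numpy()
    y = np.asarray(y_cal, float).ravel()
    rng = np.random.default_rng(seed)
    r2s, rmses = [], []
    for _ in range(n_repeats):
        y_perm = y[rng.permutation(len(y))]
        cv = repeated_kfold_cv(x, y_perm, config.mode, c, epsilon,
                               config.cv_folds, config.cv_repeats,
                               config.seed)
        r2s.append(cv["r2_cv"])
        rmses.append(cv["rmse_cv"])
    return {"mean_r2_cv": float(np.mean(r2s)),
            "mean_rmse_cv": float(np.mean(rmses)),
            "r2_cv": r2s, "rmse_cv": rmses}


def learning_curve(calibration: pd.DataFrame, y_cal: pd.Series,
                   test: pd.DataFrame, y_test: pd.Series,
                   selected: list[str], c: float, epsilon: float | None,
                   selection_order: list[str], step: int = 5,
                   min_size: int = 10, cv_folds: int = 5,
                   cv_repeats: int = 5, seed: int = 0) -> pd.DataFrame:
    """Calibration/CV/test RMSE versus calibration-subset size.

    Subsets grow in Kennard–Stone selection order; the hyperparameters
    (C, ε) of the full calibration model are reused at every size. The
    final row uses the complete calibration set.
    """
    cal_order = [s for s in selection_order if s in set(calibration.index)]
    sizes = list(range(min(min_size, len(cal_order)), len(cal_order), step))
    if not sizes or sizes[-1] != len(cal_order):
        sizes.append(len(cal_order))
    rows = []
    for size in sizes:
        ids = cal_order[:size]
        sub = calibration.loc[ids, selected]
        y_sub = np.asarray(y_cal.loc[ids], float)
        scaler = Autoscaler.fit(sub)
        x = scaler.transform(sub).to_numpy()
        est = _make_estimator("epsilon_regression", c, epsilon)
        est.fit(x, y_sub)
        pred_cal = est.predict(x)
        x_test = scaler.transform(test[selected]).to_numpy()
        pred_test = est.predict(x_test)
        cv = repeated_kfold_cv(x, y_sub, "epsilon_regression", c, epsilon,
                               min(cv_folds, size), cv_repeats, seed)
        rows.append({"n_samples": size,
                     "rmse_cal": rmse(y_sub, pred_cal),
                     "rmse_cv": cv["rmse_cv"],
                     "rmse_test": rmse(np.asarray(y_test, float), pred_test),
                     "r2_test": r_squared(np.asarray(y_test, float), pred_test)})
    return pd.DataFrame(rows)


def prediction_interval(residuals, confidence: float = 0.95) -> float:
    """Half-width of the Student-t predictive interval (± minutes).

    half-width = t(1−α/2, n−1) · sd(residuals) · sqrt(1 + 1/n)
    """
    residuals = np.asarray(residuals, float).ravel()
    n = len(residuals)
    if n < 3:
        raise TooFew("need >= 3 residuals")
    alpha = 1.0 - confidence
    t_val = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    sd = residuals.std(ddof=1)
    return float(t_val * sd * np.sqrt(1.0 + 1.0 / n))
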