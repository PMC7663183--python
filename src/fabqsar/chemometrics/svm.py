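"""Linear-kernel SVM training with grid search under repeated k-fold CV.

Regression uses the epsilon-insensitive SVR; the (C, ε) grid is
10 × 9 = 90 log-spaced pairs (C in 10^-5..10^4, ε in 10^-3..10^1 at half-
decade steps) and each pair is scored by the mean RMSE of repeated
random 5-fold CV with 20 repeats. Classification (species mode) uses
C-SVM over the same C grid scored by CV MCC. The winning parameters are
refit on the full calibration set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import DegenerateResponse
from .metrics import mcc as mcc_metric
from .metrics import r_squared, rmse, sensitivity_specificity
from .scaling import Autoscaler

C_GRID = tuple(10.0 ** k for k in range(-5, 5))            # 10 values
EPSILON_GRID = tuple(10.0 ** (k / 2) for k in range(-6, 3))  # 9 values


@dataclass
class SvmConfig:
    mode: str = "epsilon_regression"   # | "c_classification"
    c_grid: tuple = C_GRID
    epsilon_grid: tuple = EPSILON_GRID
    cv_folds: int = 5
    cv_repeats: int = 20
    max_iter: int = 20000   # libsvm iteration cap; bounds pathological cells
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("epsilon_regression", "c_classification"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.cv_folds < 2:
            raise ValueError("cv folds >= 2 required")

    def grid(self) -> list[tuple[float, float | None]]:
        if self.mode == "epsilon_regression":
            return [(c, e) for c in self.c_grid for e in self.epsilon_grid]
        return [(c, None) for c in self.c_grid]


@dataclass
class ModelBundle:
    """A fitted model plus everything needed to reapply and audit it."""

    mode: str
    selected: list[str]
    scaler: Autoscaler
    c: float
    epsilon: float | None
    coef: np.ndarray
    intercept: float | np.ndarray
    metrics: dict = field(default_factory=dict)
    grid_report: pd.DataFrame | None = None
    classes: list | None = None
    estimator: object | None = None

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        x = self.scaler.transform(frame[self.selected]).to_numpy()
        if self.estimator is not None:
            return self.estimator.predict(x)
        # rebuilt from JSON: linear regression form only
        return x @ np.asarray(self.coef) + float(np.ravel(self.intercept)[0])

    def to_json(self, path=None) -> str:
        payload = {
            "mode": self.mode, "selected": self.selected,
            "scaling": self.scaler.to_dict(),
            "hyperparameters": {"C": self.c, "epsilon": self.epsilon},
            "coef": np.asarray(self.coef).tolist(),
            "intercept": np.asarray(self.intercept).tolist(),
            "metrics": _jsonable(self.metrics),
            "classes": _jsonable(self.classes),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _make_estimator(mode: str, c: float, epsilon: float | None,
                    max_iter: int = 20000):
    from sklearn.svm import SVC, SVR

    if mode == "epsilon_regression":
        return SVR(kernel="linear", C=c, epsilon=epsilon, max_iter=max_iter)
    return SVC(kernel="linear", C=c, max_iter=max_iter)


def repeated_kfold_cv(x: np.ndarray, y: np.ndarray, mode: str, c: float,
                      epsilon: float | None, folds: int, repeats: int,
                      seed: int, max_iter: int = 20000) -> dict[str, float]:
    """Mean CV metrics over repeats × shuffled k-folds (seeded)."""
    import warnings as _warnings

    from sklearn.model_selection import KFold

    rmses, r2s, mccs = [], [], []
    _warnings.filterwarnings("ignore", message=".*max_iter.*")
    _warnings.filterwarnings("ignore", category=UserWarning,
                             module="sklearn")
    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        pred = np.empty(len(y), dtype=object if mode == "c_classification"
                        else float)
        for train, test in kf.split(x):
            est = _make_estimator(mode, c, epsilon, max_iter)
            est.fit(x[train], y[train])
            pred[test] = est.predict(x[test])
        if mode == "epsilon_regression":
            pred = pred.astype(float)
            rmses.append(rmse(y, pred))
            r2s.append(r_squared(y, pred))
        else:
            mccs.append(mcc_metric(y, pred))
    if mode == "epsilon_regression":
        return {"rmse_cv": float(np.mean(rmses)), "r2_cv": float(np.mean(r2s))}
    return {"mcc_cv": float(np.mean(mccs))}


def svm_train_grid(calibration: pd.DataFrame, y_cal: pd.Series,
                   test: pd.DataFrame | None = None,
                   y_test: pd.Series | None = None,
                   selected: list[str] | None = None,
                   config: SvmConfig | None = None) -> ModelBundle:
    """Grid-search a linear SVM on the calibration set and refit.

    Regression selects the (C, ε) pair minimising mean CV RMSE;
    classification maximises CV MCC over the C grid. Autoscaling is
    fitted on the calibration set only.
    """
    config = config or SvmConfig()
    selected = list(calibration.columns) if selected is None else selected
    if not selected:
        raise ValueError("selected descriptor list is empty")
    frame = calibration[selected]
    scaler = Autoscaler.fit(frame)
    x = scaler.transform(frame).to_numpy()

    if config.mode == "epsilon_regression":
        y = np.asarray(y_cal, float).ravel()
        if np.ptp(y) == 0:
            raise DegenerateResponse("constant response")
    else:
        y = np.asarray(y_cal).ravel()
        if len(set(y)) < 2:
            raise DegenerateResponse("single-class response")

    rows = []
    for c, eps in config.grid():
        cv = repeated_kfold_cv(x, y, config.mode, c, eps, config.cv_folds,
                               config.cv_repeats, config.seed,
                               config.max_iter)
        rows.append({"C": c, "epsilon": eps, **cv})
    report = pd.DataFrame(rows)
    if config.mode == "epsilon_regression":
        best = report.loc[report["rmse_cv"].idxmin()]
    else:
        best = report.loc[report["mcc_cv"].idxmax()]
    c_best = float(best["C"])
    eps_best = None if config.mode == "c_classification" else float(best["epsilon"])

    est = _make_estimator(config.mode, c_best, eps_best, config.max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(x, y)
    coef = np.asarray(est.coef_)
    intercept = est.intercept_ if np.size(est.intercept_) > 1 else float(
        np.asarray(est.intercept_).ravel()[0])

    bundle = ModelBundle(
        mode=config.mode, selected=selected, scaler=scaler, c=c_best,
        epsilon=eps_best, coef=coef.ravel() if config.mode == "epsilon_regression"
        else coef, intercept=intercept, grid_report=report,
        classes=None if config.mode == "epsilon_regression"
        else list(est.classes_), estimator=est)

    pred_cal = bundle.predict(calibration)
    if config.mode == "epsilon_regression":
        m = {"rmse_cal": rmse(y, pred_cal), "r2_cal": r_squared(y, pred_cal),
             "rmse_cv": float(best["rmse_cv"]), "r2_cv": float(best["r2_cv"])}
        if test is not None:
            pred_test = bundle.predict(test)
            yt = np.asarray(y_test, float).ravel()
            m["rmse_test"] = rmse(yt, pred_test)
            m["r2_test"] = r_squared(yt, pred_test)
    else:
        m = {"mcc_cal": mcc_metric(y, pred_cal),
             "mcc_cv": float(best["mcc_cv"]),
             "per_class_cal": sensitivity_specificity(y, pred_cal)}
        if test is not None:
            pred_test = bundle.predict(test)
            yt = np.asarray(y_test).ravel()
            m["mcc_test"] = mcc_metric(yt, pred_test)
            m["per_class_test"] = sensitivity_specificity(yt, pred_test)
    bundle.metrics = m
    return bundle
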