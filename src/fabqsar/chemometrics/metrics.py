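"""Regression and classification performance metrics.

R² is the coefficient of determination 1 − SS_res/SS_tot and is allowed
to go negative: prediction error larger than the response's own variance
is a meaningful diagnostic (it is how overfit models reveal themselves
on external test sets). The Matthews correlation coefficient uses the
generalised multiclass (Gorodkin) formula, which reduces to the textbook
binary MCC for two classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import EmptyInput


def rmse(y_true, y_pred) -> float:
    y_true, y_pred = _check(y_true, y_pred)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true, y_pred) -> float:
    y_true, y_pred = _check(y_true, y_pred)
    ss_res = float(((y_true - y_pred) ** 2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _check(y_true, y_pred):
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if len(y_true) == 0:
        raise EmptyInput("empty inputs")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    return y_true, y_pred


def confusion_matrix(y_true, y_pred, labels=None) -> pd.DataFrame:
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) == 0:
        raise EmptyInput("empty inputs")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    mat = pd.DataFrame(0, index=labels, columns=labels)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    return mat


def mcc(y_true, y_pred) -> float:
    """Generalised (Gorodkin) Matthews correlation coefficient.

    With confusion matrix C: cov(true, pred) / sqrt(cov(true,true) ·
    cov(pred,pred)) over the class indicator variables; 0 when either
    marginal is degenerate.
    """
    c = confusion_matrix(y_true, y_pred).to_numpy(dtype=float)
    n = c.sum()
    correct = np.trace(c)
    t_k = c.sum(axis=1)  # true counts per class
    p_k = c.sum(axis=0)  # predicted counts per class
    cov_tp = correct * n - t_k @ p_k
    cov_tt = n * n - t_k @ t_k
    cov_pp = n * n - p_k @ p_k
    denom = np.sqrt(cov_tt * cov_pp)
    return float(cov_tp / denom) if denom > 0 else 0.0


def sensitivity_specificity(y_true, y_pred) -> dict[str, dict[str, float]]:
    """Per-class sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    cm = confusion_matrix(y_true, y_pred)
    mat = cm.to_numpy(dtype=float)
    total = mat.sum()
    out = {}
    for i, label in enumerate(cm.index):
        tp = mat[i, i]
        fn = mat[i].sum() - tp
        fp = mat[:, i].sum() - tp
        tn = total - tp - fn - fp
        out[str(label)] = {
            "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
        }
    return out


def metrics(y_true, y_pred, mode: str = "regression") -> dict:
    """Bundle of the diagnostics used throughout model development."""
    if mode == "regression":
        return {"rmse": rmse(y_true, y_pred), "r2": r_squared(y_true, y_pred)}
    if mode == "classification":
        return {"mcc": mcc(y_true, y_pred),
                "per_class": sensitivity_specificity(y_true, y_pred)}
    raise ValueError(f"unknown mode {mode!r}")
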