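"""PLS1 regression via NIPALS, with nested component counts.

For a single response the NIPALS sequence is closed-form per component
(no inner iteration): w_k = X'y/||X'y||, t_k = Xw_k, p_k = X't/t't,
q_k = y't/t't, then X and y are deflated. Regression coefficients are
available for every component count 1..A from one fit, which makes
cross-validated latent-variable selection cheap.

At full rank the A-component PLS predictor coincides with the ordinary
least-squares fit — a property the test suite checks against a
normal-equations oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class PlsModel:
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # (p, A)
    loadings: np.ndarray   # (p, A)
    scores: np.ndarray     # (n, A)
    q: np.ndarray          # (A,)
    coefs: np.ndarray      # (p, A): column k-1 = coefficients with k comps

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        k = self.n_components if n_components is None else n_components
        return self.coefs[:, k - 1]

    def predict(self, x: np.ndarray, n_components: int | None = None
                ) -> np.ndarray:
        b = self.coefficients(n_components)
        return (np.asarray(x, float) - self.x_mean) @ b + self.y_mean


def pls_fit(x: np.ndarray, y: np.ndarray, n_components: int,
            tol: float = 1e-12) -> PlsModel:
    """Fit a PLS1 model with up to ``n_components`` latent variables.

    Components beyond the effective rank of X are capped with a warning
    (deflation leaves nothing to extract).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float).ravel()
    n, p = x.shape
    max_rank = min(n - 1, p) if n > 1 else 1
    if n_components > max_rank:
        warnings.warn(f"n_components capped at rank {max_rank}", UserWarning)
        n_components = max_rank
    x_mean, y_mean = x.mean(0), float(y.mean())
    xc = x - x_mean
    yc = y - y_mean

    ws, ps, ts, qs = [], [], [], []
    for _ in range(n_components):
        w = xc.T @ yc
        norm = np.linalg.norm(w)
        if norm < tol:
            break
        w /= norm
        t = xc @ w
        tt = t @ t
        if tt < tol:
            break
        pvec = xc.T @ t / tt
        qval = yc @ t / tt
        xc = xc - np.outer(t, pvec)
        yc = yc - qval * t
        ws.append(w)
        ps.append(pvec)
        ts.append(t)
        qs.append(qval)

    if not ws:
        # y orthogonal to X (or X constant): intercept-only model
        zeros = np.zeros((p, 1))
        return PlsModel(x_mean, y_mean, zeros, zeros,
                        np.zeros((n, 1)), np.zeros(1), zeros)

    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    t_mat = np.column_stack(ts)
    q_vec = np.asarray(qs)
    # B_k = W_k (P_k' W_k)^-1 q_k for each nested component count
    coefs = np.empty((p, len(ws)))
    for k in range(1, len(ws) + 1):
        wk, pk, qk = w_mat[:, :k], p_mat[:, :k], q_vec[:k]
        coefs[:, k - 1] = wk @ np.linalg.solve(pk.T @ wk, qk)
    return PlsModel(x_mean, y_mean, w_mat, p_mat, t_mat, q_vec, coefs)


def _nested_coefs(x: np.ndarray, y: np.ndarray, max_components: int,
                  tol: float = 1e-12
                  ) -> tuple[np.ndarray, float, np.ndarray]:
    """NIPALS PLS1 returning (x_mean, y_mean, B) where column k-1 of B
    holds the regression coefficients of the k-component model.

    Uses the R-weight recursion r_k = w_k − Σ_{j<k} r_j (p_j·w_k), so
    B_k = Σ_{j≤k} r_j q_j accumulates without any solve.
    """
    x_mean = x.mean(0)
    y_mean = y.mean()
    xc = x - x_mean
    yc = y - y_mean
    p_dim = x.shape[1]
    coefs = np.zeros((p_dim, max_components))
    rs, ps = [], []
    b = np.zeros(p_dim)
    k_eff = 0
    for k in range(max_components):
        w = xc.T @ yc
        norm = np.linalg.norm(w)
        if norm < tol:
            break
        w /= norm
        t = xc @ w
        tt = t @ t
        if tt < tol:
            break
        pvec = xc.T @ t / tt
        qval = yc @ t / tt
        xc -= np.outer(t, pvec)
        yc -= qval * t
        r = w.copy()
        for rj, pj in zip(rs, ps):
            r -= rj * (pj @ w)
        rs.append(r)
        ps.append(pvec)
        b = b + qval * r
        coefs[:, k] = b
        k_eff = k + 1
    for k in range(k_eff, max_components):
        coefs[:, k] = b  # deflation exhausted: later counts reuse B_keff
    return x_mean, y_mean, coefs


def make_cv_folds(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffled k-fold test-index arrays (sklearn KFold layout)."""
    from sklearn.model_selection import KFold

    kf = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.empty((n, 1)))]


def cv_rmse_pls(x: np.ndarray, y: np.ndarray, max_components: int,
                n_folds: int = 5, seed: int = 0,
                folds: list[np.ndarray] | None = None) -> tuple[float, int]:
    """K-fold CV RMSE of PLS1, minimised over the component count.

    Returns (best RMSE, best component count). Fold assignment is a
    seeded shuffle (or precomputed ``folds``); one NIPALS fit per fold
    covers every component count, and predictions for all counts come
    from a single matrix product.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if folds is None:
        folds = make_cv_folds(n, n_folds, seed)
    max_components = max(1, min(max_components, x.shape[1], n - 2))
    sq_err = np.zeros(max_components)
    mask = np.ones(n, dtype=bool)
    for test in folds:
        mask[:] = True
        mask[test] = False
        x_mean, y_mean, coefs = _nested_coefs(x[mask].copy(), y[mask].copy(),
                                              max_components)
        pred = (x[test] - x_mean) @ coefs + y_mean  # (n_test, k)
        sq_err += ((pred - y[test, None]) ** 2).sum(0)
    rmse_per_k = np.sqrt(sq_err / n)
    best = int(np.argmin(rmse_per_k))
    return float(rmse_per_k[best]), best + 1
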