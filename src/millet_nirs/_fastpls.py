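"""Minimal PLS1 regression for the wavelength-search hot loop.

The subset search evaluates hundreds of thousands of small cross-validated
PLS fits; this NIPALS implementation avoids per-call estimator overhead by
working directly on ndarrays. It is validated against
sklearn.cross_decomposition.PLSRegression in the test suite and is used
only inside the selection fitness; the calibration models themselves are
built with scikit-learn.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pls1_coefficients", "pls1_fit_predict", "cv_mse"]


def pls1_coefficients(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1 on centred data; returns (coef, x_mean, y_mean).

    Predictions are ``(X_new - x_mean) @ coef + y_mean``. Deflation stops
    early when the residual X or y carries no usable covariance, so the
    effective number of components never exceeds the data rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    n, p = Xc.shape
    a_max = min(n_components, p, n - 1)
    W = np.empty((p, a_max))
    P = np.empty((p, a_max))
    q = np.empty(a_max)
    eps = np.finfo(float).eps
    x_scale = max(np.abs(Xc).max(), eps)
    y_scale = max(np.abs(yc).max(), eps)
    used = 0
    for a in range(a_max):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= eps * p * x_scale * y_scale:
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        if tt <= eps * n * x_scale**2:
            break
        p_a = (Xc.T @ t) / tt
        q_a = (yc @ t) / tt
        Xc = Xc - np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        used = a + 1
    if used == 0:
        return np.zeros(p), x_mean, y_mean
    W, P, q = W[:, :used], P[:, :used], q[:used]
    # B = W (P^T W)^{-1} q ; P^T W is upper triangular with unit-ish diag
    coef = W @ np.linalg.solve(P.T @ W, q)
    return coef, x_mean, y_mean


def pls1_fit_predict(X_train, y_train, X_test, n_components: int) -> np.ndarray:
    coef, x_mean, y_mean = pls1_coefficients(X_train, y_train, n_components)
    return (np.asarray(X_test, dtype=float) - x_mean) @ coef + y_mean


def kfold_indices(n: int, n_splits: int, seed: int):
    """Seeded shuffled k-fold index pairs, deterministic for fixed seed."""
    order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, n_splits)
    out = []
    for i in range(n_splits):
        test = folds[i]
        train = np.concatenate([folds[j] for j in range(n_splits) if j != i])
        out.append((train, test))
    return out


def cv_mse(X, y, n_components: int, folds) -> tuple[float, float]:
    """Mean over folds of fold MSE, and mean of fold RMSE."""
    mses = []
    for train, test in folds:
        pred = pls1_fit_predict(X[train], y[train], X[test], n_components)
        mses.append(float(np.mean((y[test] - pred) ** 2)))
    mses = np.asarray(mses)
    return float(mses.mean()), float(np.sqrt(mses).mean())
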