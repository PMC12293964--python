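"""Lightweight least-squares helpers used in hot loops.

The public modeling API fits through statsmodels; the greedy candidate scans,
VIF gates and cross-validation loops only need R-squared and predictions, for
which a plain ``lstsq`` is an order of magnitude faster.
"""

from __future__ import annotations

import numpy as np


def design_matrix(table, predictors: list[str]) -> np.ndarray:
    """Column-stacked predictors with a leading intercept column."""
    n = len(table)
    if predictors:
        X = np.column_stack(
            [np.ones(n)] + [table[p].to_numpy(dtype=float) for p in predictors]
        )
    else:
        X = np.ones((n, 1))
    return X


def ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    beta = ols_beta(X, y)
    resid = y - X @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("outcome has zero variance")
    return 1.0 - float((resid**2).sum()) / sst


def aux_r2(X_others: np.ndarray, x: np.ndarray) -> float:
    """R-squared of one predictor regressed on others (incl. intercept)."""
    beta = ols_beta(X_others, x)
    resid = x - X_others @ beta
    sst = float(((x - x.mean()) ** 2).sum())
    if sst == 0:
        return 1.0
    return 1.0 - float((resid**2).sum()) / sst


def vif_from_matrix(X_noconst: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R2_j) for each column regressed on the rest.

    Perfect collinearity yields ``inf`` rather than an exception.
    """
    n, k = X_noconst.shape
    out = np.empty(k)
    ones = np.ones((n, 1))
    for j in range(k):
        others = np.column_stack(
            [ones, X_noconst[:, [i for i in range(k) if i != j]]]
        )
        r2 = aux_r2(others, X_noconst[:, j])
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out
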