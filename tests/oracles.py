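"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computational paths: multiple
correlation via an explicit least-squares design matrix, best-subset search
by naive enumeration over that oracle, and the L1 SVM as a differently
parameterized linear program (epigraph formulation with free weights).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def ols_multiple_correlation(X: np.ndarray, y: np.ndarray) -> float:
    """sqrt(R^2) of y regressed on X plus intercept, via lstsq."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst
    return float(np.sqrt(max(0.0, min(1.0, r2))))


def brute_force_best_subset(X: np.ndarray, y: np.ndarray, k: int):
    """Enumerate all k-subsets with the OLS oracle; first maximum wins."""
    p = X.shape[1]
    best_idx, best_corr = None, -1.0
    for subset in itertools.combinations(range(p), k):
        corr = ols_multiple_correlation(X[:, subset], y)
        if corr > best_corr + 1e-12:
            best_idx, best_corr = subset, corr
    return best_idx, best_corr


def epigraph_l1_svm_objective(X: np.ndarray, y01: np.ndarray,
                              c_pos: float, c_neg: float) -> float:
    """Optimal objective of the class-weighted L1 soft-margin SVM.

    Epigraph formulation: free weights w with auxiliary t >= |w|,
    min sum(t) + sum(C_i xi_i) subject to the margin constraints.
    """
    X = np.asarray(X, dtype=float)
    y = np.where(np.asarray(y01) > 0, 1.0, -1.0)
    n, p = X.shape
    # variables: [w (p, free), t (p), b (free), xi (n)]
    cost = np.concatenate([np.zeros(p), np.ones(p), [0.0],
                           np.where(y > 0, c_pos, c_neg)])
    rows = []
    rhs = []
    # w - t <= 0 and -w - t <= 0
    for sign in (1.0, -1.0):
        block = np.hstack([sign * np.eye(p), -np.eye(p),
                           np.zeros((p, 1)), np.zeros((p, n))])
        rows.append(block)
        rhs.append(np.zeros(p))
    # -y_i (w.x_i + b) - xi_i <= -1
    margin = np.hstack([-y[:, None] * X, np.zeros((n, p)),
                        -y[:, None], -np.eye(n)])
    rows.append(margin)
    rhs.append(-np.ones(n))
    A_ub = np.vstack(rows)
    b_ub = np.concatenate(rhs)
    bounds = ([(None, None)] * p + [(0, None)] * p
              + [(None, None)] + [(0, None)] * n)
    res = linprog(cost, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    assert res.success, res.message
    return float(res.fun)
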