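"""Class-weighted 1-norm (L1) soft-margin linear SVM via linear programming.

The classifier minimizes

    ||w||_1  +  C_pos * sum_{i: y_i = +1} xi_i  +  C_neg * sum_{i: y_i = -1} xi_i

subject to  y_i (w . x_i + b) >= 1 - xi_i,  xi_i >= 0,

with labels coded +1 (severe) / -1 (non-severe). The L1 penalty on the
weights induces sparsity, so the fitted hyper-plane doubles as a feature
selector. The problem is solved exactly as a linear program through the
standard positive/negative split w = w+ - w-; the offset b is a free,
unpenalized variable. Class penalties follow the prevalence-balancing rule:
the positive class's penalty is the negative/positive count ratio, the other
class's penalty is 1, so the minority (severe) class is up-weighted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import AlignmentError, DegenerateDataError, SepsiPanelError
from .preprocess import NormalizationParams

#: Weights smaller than this in absolute value are reported as exactly zero.
WEIGHT_TOL = 1e-8


@dataclass
class LinearModel:
    """Linear decision function w . x_norm + b over normalized features.

    ``norm_params`` holds the raw-scale means/SDs so raw measurements can be
    scored directly; a model fitted on already-normalized data carries
    identity parameters.
    """

    feature_names: tuple[str, ...]
    weights: np.ndarray
    bias: float
    norm_params: NormalizationParams
    penalties: tuple[float, float] | None = None  # (C_pos, C_neg)
    penalty_convention: str = "positive=N_neg/N_pos, negative=1.0"
    weight_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.feature_names) != self.weights.size:
            raise AlignmentError("weights and feature_names lengths differ")
        if self.norm_params.feature_names != tuple(self.feature_names):
            raise AlignmentError("norm_params feature names differ from the model's")

    @property
    def n_nonzero_weights(self) -> int:
        return int(np.count_nonzero(self.weights))

    def to_json(self, path, provenance: str = "") -> None:
        doc = {
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "normalization": self.norm_params.to_dict(),
            "penalties": list(self.penalties) if self.penalties else None,
            "penalty_convention": self.penalty_convention,
            "weight_se": self.weight_se.tolist() if self.weight_se is not None else None,
            "provenance": provenance,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            feature_names=tuple(doc["feature_names"]),
            weights=np.asarray(doc["weights"]),
            bias=float(doc["bias"]),
            norm_params=NormalizationParams.from_dict(doc["normalization"]),
            penalties=tuple(doc["penalties"]) if doc.get("penalties") else None,
            penalty_convention=doc.get("penalty_convention", ""),
            weight_se=(np.asarray(doc["weight_se"])
                       if doc.get("weight_se") is not None else None),
        )


@dataclass
class FitDiagnostics:
    objective_value: float
    slacks: np.ndarray = field(repr=False)
    n_nonzero_weights: int = 0


def class_penalties(y, positive_upweighted: bool = True) -> tuple[float, float]:
    """Prevalence-balancing penalties (C_pos, C_neg).

    Default convention: C_pos = N_neg / N_pos, C_neg = 1.0, up-weighting the
    positive class when it is the minority. ``positive_upweighted=False``
    swaps the roles (C_pos = 1.0, C_neg = N_pos / N_neg).
    """
    y = np.asarray(y)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0) + np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("both classes must be present to set penalties")
    if positive_upweighted:
        return n_neg / n_pos, 1.0
    return 1.0, n_pos / n_neg


def fit_l1_svm(X_norm, y, penalties: tuple[float, float] | None = None,
               norm_params: NormalizationParams | None = None,
               ) -> tuple[LinearModel, FitDiagnostics]:
    """Fit the L1-penalized soft-margin linear SVM by linear programming.

    ``X_norm`` is an already-normalized feature matrix (DataFrame or array);
    ``y`` uses 0/1 (or -1/+1) labels. ``penalties`` defaults to the
    prevalence-balancing rule. The LP is solved with HiGHS; weights below
    ``WEIGHT_TOL`` in magnitude are truncated to exactly zero.
    """
    if isinstance(X_norm, pd.DataFrame):
        names = tuple(X_norm.columns)
        X = X_norm.to_numpy(dtype=float)
    else:
        X = np.asarray(X_norm, dtype=float)
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    y = np.asarray(y)
    y_pm = np.where(y > 0, 1.0, -1.0)
    n, p = X.shape
    if np.unique(y_pm).size < 2:
        raise DegenerateDataError("both classes must be present for training")
    if penalties is None:
        penalties = class_penalties(y)
    c_pos, c_neg = penalties

    # variables: [w+ (p), w- (p), b (1, free), xi (n)]
    cost = np.concatenate([np.ones(2 * p), [0.0],
                           np.where(y_pm > 0, c_pos, c_neg)])
    # -y_i (w . x_i + b) - xi_i <= -1
    A_ub = np.hstack([
        -y_pm[:, None] * X,
        y_pm[:, None] * X,
        -y_pm[:, None],
        -np.eye(n),
    ])
    b_ub = -np.ones(n)
    bounds = [(0, None)] * (2 * p) + [(None, None)] + [(0, None)] * n
    res = linprog(cost, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise SepsiPanelError(f"LP solver failed: {res.message} (status {res.status})")

    w = res.x[:p] - res.x[p:2 * p]
    w[np.abs(w) < WEIGHT_TOL] = 0.0
    bias = float(res.x[2 * p])
    slacks = np.clip(res.x[2 * p + 1:], 0.0, None)
    if norm_params is None:
        norm_params = NormalizationParams.identity(names)
    model = LinearModel(feature_names=names, weights=w, bias=bias,
                        norm_params=norm_params, penalties=(c_pos, c_neg))
    diag = FitDiagnostics(objective_value=float(res.fun), slacks=slacks,
                          n_nonzero_weights=model.n_nonzero_weights)
    return model, diag


def decision_score(x, model: LinearModel):
    """Severity score sum_i w_i (x_i - mu_i)/sigma_i + b for raw input.

    ``x`` may be a single p-vector, a 2-D array (rows scored independently),
    or a DataFrame (columns aligned by name; mismatch raises
    :class:`AlignmentError`).
    """
    if isinstance(x, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in x.columns]
        if missing:
            raise AlignmentError(f"input lacks model features: {missing}")
        x = x.loc[:, list(model.feature_names)].to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != len(model.feature_names):
        raise AlignmentError(
            f"input has {x2.shape[1]} features, model expects {len(model.feature_names)}")
    z = (x2 - model.norm_params.mean) / model.norm_params.sd
    scores = z @ model.weights + model.bias
    return float(scores[0]) if squeeze else scores


def classify(score):
    """Severity diagnosis: 1 iff the score is greater than or equal to zero."""
    arr = np.asarray(score)
    out = (arr >= 0).astype(int)
    return int(out) if arr.ndim == 0 else out
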