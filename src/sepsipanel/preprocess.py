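"""Feature normalization, severity labels, splits and group correlations.

Every biomarker is rescaled to zero mean and unit sample standard deviation
(n-1 denominator) before selection or model fitting, and the removed
mean/SD pairs are retained so that new raw measurements can be scored with a
stored model. Correlation heatmap inputs are computed separately per severity
group, since the study's electrolyte and angiopoietin correlation structure
differs sharply between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateDataError, SchemaError


@dataclass(frozen=True)
class NormalizationParams:
    """Per-variable location/scale removed by normalization."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if not (len(self.feature_names) == self.mean.size == self.sd.size):
            raise SchemaError("feature_names, mean and sd must have equal lengths")
        if np.any(self.sd <= 0):
            bad = self.feature_names[int(np.argmax(self.sd <= 0))]
            raise DegenerateDataError(f"non-positive SD for variable {bad!r}")

    def to_dict(self) -> dict:
        return {"feature_names": list(self.feature_names),
                "mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(tuple(d["feature_names"]), np.asarray(d["mean"]), np.asarray(d["sd"]))

    @classmethod
    def identity(cls, feature_names) -> "NormalizationParams":
        p = len(feature_names)
        return cls(tuple(feature_names), np.zeros(p), np.ones(p))


@dataclass(frozen=True)
class SplitPlan:
    """One random train/test division: test third, train two-thirds."""

    test_indices: np.ndarray
    train_indices: np.ndarray
    seed: int


def _check_frame(X: pd.DataFrame) -> pd.DataFrame:
    if X.isna().any().any():
        bad = [c for c in X.columns if X[c].isna().any()]
        raise SchemaError(f"missing values in columns {bad}; resolve missingness upstream")
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise DegenerateDataError(f"need at least 2 rows and 1 column, got {X.shape}")
    return X


def normalize(X: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationParams]:
    """Rescale each column to zero mean and unit sample SD (ddof=1).

    Returns the normalized frame and the removed per-column mean/SD.
    Raises :class:`DegenerateDataError` for a constant column.
    """
    _check_frame(X)
    mean = X.mean(axis=0).to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1).to_numpy(dtype=float)
    if np.any(sd == 0):
        bad = X.columns[int(np.argmax(sd == 0))]
        raise DegenerateDataError(f"column {bad!r} is constant and cannot be normalized")
    params = NormalizationParams(tuple(X.columns), mean, sd)
    return (X - mean) / sd, params


def apply_normalization(X: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """(x - mean) / sd columnwise using stored parameters."""
    if tuple(X.columns) != params.feature_names:
        raise AlignmentError(
            f"feature names do not match params: {tuple(X.columns)} vs {params.feature_names}")
    return (X - params.mean) / params.sd


def invert_normalization(X_norm: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Inverse of :func:`apply_normalization`."""
    if tuple(X_norm.columns) != params.feature_names:
        raise AlignmentError("feature names do not match params")
    return X_norm * params.sd + params.mean


def split_train_test(n: int, seed: int) -> SplitPlan:
    """Uniform random split with round(n/3) test rows and the rest training."""
    if n < 3:
        raise DegenerateDataError(f"need at least 3 rows to split, got {n}")
    n_test = round(n / 3)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = np.sort(perm[:n_test])
    train = np.sort(perm[n_test:])
    return SplitPlan(test_indices=test, train_indices=train, seed=seed)


def group_correlations(X: pd.DataFrame, y: np.ndarray) -> dict[int, pd.DataFrame]:
    """Pairwise Pearson correlation matrices, one per severity group.

    Mirrors the study's group-wise correlation heatmaps: the contrast between
    the two matrices (electrolyte block, Ang pair) is the scientific content.
    """
    _check_frame(X)
    y = np.asarray(y)
    if len(y) != len(X):
        raise SchemaError("label vector length does not match the feature matrix")
    out: dict[int, pd.DataFrame] = {}
    for g in (0, 1):
        rows = X.loc[np.asarray(y == g)]
        if len(rows) < 3:
            raise DegenerateDataError(
                f"group {g} has {len(rows)} rows; at least 3 are required")
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(rows.to_numpy(dtype=float), rowvar=False)
        corr = np.clip(corr, -1.0, 1.0)
        np.fill_diagonal(corr, 1.0)
        out[g] = pd.DataFrame(corr, index=X.columns, columns=X.columns)
    return out
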