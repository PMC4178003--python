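"""Random-forest permutation importance (mean decrease in accuracy).

A forest of CART trees is grown on bootstrap resamples (tree induction is
delegated to scikit-learn's ``DecisionTreeClassifier``; bootstrap and
out-of-bag bookkeeping are handled here so OOB rows are explicit per tree).
Feature importance is the OOB permutation measure: for each tree, the
accuracy on its untouched OOB rows minus the accuracy after randomly
permuting one feature's OOB values; the mean over trees is the feature's
mean decrease in accuracy (MDA). Gini importance is also computed for
reference but ranking uses MDA, which is the more reliable measure for
correlated biomarker panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateDataError, SchemaError

MAX_REDRAWS = 100


@dataclass
class Forest:
    trees: list[DecisionTreeClassifier] = field(repr=False)
    oob_indices: list[np.ndarray] = field(repr=False)
    feature_names: tuple[str, ...] = ()
    n_trees: int = 0
    seed: int | None = None
    n_redrawn: int = 0


@dataclass
class ImportanceRanking:
    """Features ordered by decreasing MDA; ranks 1..p."""

    entries: pd.DataFrame  # columns: feature, mda, rank (sorted by rank)
    n_trees: int
    seed: int | None
    gini: pd.Series | None = None
    n_skipped_tree_features: int = 0

    def mda(self, feature: str) -> float:
        row = self.entries[self.entries["feature"] == feature]
        if row.empty:
            raise SchemaError(f"unknown feature {feature!r}")
        return float(row["mda"].iloc[0])

    def rank(self, feature: str) -> int:
        row = self.entries[self.entries["feature"] == feature]
        if row.empty:
            raise SchemaError(f"unknown feature {feature!r}")
        return int(row["rank"].iloc[0])


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        Xv = X.to_numpy(dtype=np.float32)
    else:
        Xv = np.asarray(X, dtype=np.float32)
        names = tuple(f"x{j}" for j in range(Xv.shape[1]))
    Xv = np.ascontiguousarray(Xv)
    y = np.asarray(y, dtype=int)
    if len(y) != Xv.shape[0]:
        raise SchemaError("X and y lengths differ")
    return Xv, y, names


def fit_forest(X, y, n_trees: int = 1000, seed: int | None = None,
               max_features: int | str = "sqrt") -> Forest:
    """Grow a classification forest with per-tree bootstrap and OOB tracking.

    Defaults follow common practice for the method: floor(sqrt(p)) candidate
    features per split, Gini criterion, trees grown to purity. A bootstrap
    resample containing a single class is redrawn.
    """
    Xv, y, names = _as_xy(X, y)
    if np.unique(y).size < 2:
        raise DegenerateDataError("both classes must be present")
    n, p = Xv.shape
    if max_features == "sqrt":
        max_features = max(1, math.floor(math.sqrt(p)))
    rng = np.random.default_rng(seed)
    trees, oob_sets = [], []
    redrawn = 0
    for _ in range(n_trees):
        for attempt in range(MAX_REDRAWS + 1):
            boot = rng.integers(0, n, size=n)
            if np.unique(y[boot]).size == 2:
                break
            redrawn += 1
        else:
            raise DegenerateDataError("could not draw a two-class bootstrap resample")
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            criterion="gini", max_features=max_features,
            random_state=int(rng.integers(2**31)))
        tree.fit(Xv[boot], y[boot])
        trees.append(tree)
        oob_sets.append(oob)
    return Forest(trees=trees, oob_indices=oob_sets, feature_names=names,
                  n_trees=n_trees, seed=seed, n_redrawn=redrawn)


def oob_error(forest: Forest, X, y) -> float:
    """Out-of-bag misclassification rate by per-sample majority vote."""
    Xv, y, _ = _as_xy(X, y)
    n = Xv.shape[0]
    votes = np.zeros((n, 2))
    for tree, oob in zip(forest.trees, forest.oob_indices):
        if oob.size == 0:
            continue
        pred = tree.predict(Xv[oob], check_input=False).astype(int)
        votes[oob, pred] += 1
    voted = votes.sum(axis=1) > 0
    pred = votes.argmax(axis=1)
    if not voted.any():
        raise DegenerateDataError("no sample was ever out-of-bag")
    return float(np.mean(pred[voted] != y[voted]))


def mda_importance(forest: Forest, X, y, seed: int | None = None) -> ImportanceRanking:
    """OOB permutation importance (mean decrease in accuracy) per feature.

    Per tree and feature: accuracy on the untouched OOB rows minus accuracy
    with that feature's OOB values permuted; MDA is the mean over trees.
    Trees with an empty OOB set are skipped (counted). A feature no tree
    splits on gets MDA exactly 0, since permuting it cannot change any
    tree's predictions.
    """
    Xv, y, names = _as_xy(X, y)
    if names != forest.feature_names:
        raise SchemaError("feature names differ from the forest's")
    p = Xv.shape[1]
    rng = np.random.default_rng(seed)
    deltas = np.zeros(p)
    used_trees = np.zeros(p)
    skipped = 0
    for tree, oob in zip(forest.trees, forest.oob_indices):
        if oob.size == 0:
            skipped += 1
            continue
        X_oob = Xv[oob]
        y_oob = y[oob]
        base = np.mean(tree.predict(X_oob, check_input=False).astype(int) == y_oob)
        tree_features = set(tree.tree_.feature[tree.tree_.feature >= 0])
        for j in range(p):
            if j not in tree_features:
                # permutation of an unused feature is a no-op: delta exactly 0
                used_trees[j] += 1
                continue
            perm = rng.permutation(oob.size)
            Xp = X_oob.copy()
            Xp[:, j] = X_oob[perm, j]
            acc = np.mean(tree.predict(Xp, check_input=False).astype(int) == y_oob)
            deltas[j] += base - acc
            used_trees[j] += 1
    if not used_trees.all():
        raise DegenerateDataError("every tree had an empty OOB set")
    mda = deltas / used_trees
    order = np.lexsort((np.arange(p), -mda))  # decreasing MDA, ties by feature order
    entries = pd.DataFrame({
        "feature": [names[j] for j in order],
        "mda": mda[order],
        "rank": np.arange(1, p + 1),
    })
    gini = pd.Series(
        np.mean([t.feature_importances_ for t in forest.trees], axis=0),
        index=list(names), name="gini_importance")
    return ImportanceRanking(entries=entries, n_trees=forest.n_trees, seed=seed,
                             gini=gini, n_skipped_tree_features=skipped)
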