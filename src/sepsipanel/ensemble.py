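"""Bagged SVM ensembles, diagnostic measures and repeated-split evaluation.

Evaluation protocol: a random third of the samples is held out as the test
set; B bootstrap resamples of the remaining two-thirds each train one
class-weighted L1 SVM; the ensemble decision is the mean of the member
decision functions (equivalently, the mean weight vector and bias),
thresholded at zero. The whole procedure is repeated R times with fresh
splits and the four diagnostic measures — sensitivity (TPR), specificity
(TNR), positive and negative predictive value (PPV/NPV) — are averaged, with
standard errors SD/sqrt(R).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SchemaError
from .preprocess import NormalizationParams, normalize, split_train_test
from .svm import LinearModel, class_penalties, fit_l1_svm

MEASURES = ("TPR", "TNR", "PPV", "NPV")

#: Maximum redraws for a bootstrap resample / split that lacks a class.
MAX_REDRAWS = 100


@dataclass
class EnsembleModel:
    """Bag of linear SVMs plus their mean (the ensemble decision function)."""

    members: list[LinearModel]
    aggregate: LinearModel
    n_redrawn_resamples: int = 0

    @property
    def B(self) -> int:
        return len(self.members)


@dataclass
class EvaluationResult:
    """Mean and standard error of each diagnostic measure over R repeats."""

    summary: pd.DataFrame       # index: measure; columns: mean, se, n_defined
    per_repeat: pd.DataFrame = field(repr=False)
    R: int = 0
    B: int = 0
    subset: tuple[str, ...] = ()
    seed: int | None = None
    n_undefined: dict[str, int] = field(default_factory=dict)
    degenerate_se: bool = False  # True when R is too small for an SE

    def mean(self, measure: str) -> float:
        return float(self.summary.loc[measure, "mean"])

    def se(self, measure: str) -> float:
        return float(self.summary.loc[measure, "se"])


def fit_bagged_ensemble(X_norm: pd.DataFrame, y, B: int = 50,
                        seed: int | None = None,
                        penalties: tuple[float, float] | None = None,
                        norm_params: NormalizationParams | None = None,
                        identity_bootstrap: bool = False) -> EnsembleModel:
    """Train B L1 SVMs on bootstrap resamples and average them.

    Resamples are the same size as the training set, drawn with replacement;
    a resample missing a class is redrawn (up to ``MAX_REDRAWS`` times).
    ``identity_bootstrap=True`` replaces every resample with the full
    training set (useful to check that a B=1 "ensemble" is a single model).
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DegenerateDataError("training data must contain both classes")
    if B < 1:
        raise DegenerateDataError("B must be at least 1")
    rng = np.random.default_rng(seed)
    n = len(X_norm)
    Xv = X_norm.to_numpy(dtype=float)
    members: list[LinearModel] = []
    redrawn = 0
    for _ in range(B):
        if identity_bootstrap:
            idx = np.arange(n)
        else:
            for attempt in range(MAX_REDRAWS + 1):
                idx = rng.integers(0, n, size=n)
                if np.unique(y[idx]).size == 2:
                    break
                redrawn += 1
            else:
                raise DegenerateDataError(
                    f"could not draw a two-class bootstrap resample in {MAX_REDRAWS} tries")
        Xb = pd.DataFrame(Xv[idx], columns=X_norm.columns)
        model, _ = fit_l1_svm(Xb, y[idx], penalties=penalties, norm_params=norm_params)
        members.append(model)
    agg_w = np.mean([m.weights for m in members], axis=0)
    agg_b = float(np.mean([m.bias for m in members]))
    aggregate = LinearModel(
        feature_names=members[0].feature_names,
        weights=agg_w, bias=agg_b,
        norm_params=members[0].norm_params,
        penalties=members[0].penalties,
    )
    return EnsembleModel(members=members, aggregate=aggregate,
                         n_redrawn_resamples=redrawn)


def prediction_measures(predictions, truths) -> dict[str, float]:
    """TPR, TNR, PPV, NPV from 0/1 predictions and truths.

    A measure with a zero denominator is reported as NaN, never silently 0.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise SchemaError(
            f"predictions and truths lengths differ: {predictions.shape} vs {truths.shape}")
    if np.unique(truths).size < 2:
        raise DegenerateDataError("truths must contain both classes")
    tp = int(np.sum((predictions == 1) & (truths == 1)))
    tn = int(np.sum((predictions == 0) & (truths == 0)))
    fp = int(np.sum((predictions == 1) & (truths == 0)))
    fn = int(np.sum((predictions == 0) & (truths == 1)))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "TPR": ratio(tp, tp + fn),
        "TNR": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
    }


def _summarize(per_repeat: pd.DataFrame, R: int) -> tuple[pd.DataFrame, dict, bool]:
    rows, undefined = [], {}
    degenerate = False
    for m in MEASURES:
        vals = per_repeat[m].to_numpy(dtype=float)
        defined = vals[~np.isnan(vals)]
        undefined[m] = int(np.isnan(vals).sum())
        if defined.size == 0:
            rows.append({"measure": m, "mean": float("nan"), "se": float("nan"),
                         "n_defined": 0})
            continue
        mean = float(defined.mean())
        if defined.size < 2:
            se = float("nan")
            degenerate = True
        else:
            se = float(defined.std(ddof=1) / np.sqrt(defined.size))
        rows.append({"measure": m, "mean": mean, "se": se, "n_defined": defined.size})
    summary = pd.DataFrame(rows).set_index("measure")
    return summary, undefined, degenerate


def repeated_evaluation(X: pd.DataFrame, y, subset, B: int = 50, R: int = 100,
                        seed: int | None = None,
                        train_only_norm: bool = False) -> EvaluationResult:
    """Repeated random-split evaluation of the bagged SVM on a feature subset.

    By default the feature matrix is normalized globally before splitting
    (the study's protocol); ``train_only_norm=True`` recomputes normalization
    parameters on the training rows of each split (leakage-safe variant).
    Per-repeat prevalence and positive-prediction rate are retained alongside
    the four measures so chance levels can be checked under permutation nulls.
    """
    y = np.asarray(y)
    subset = tuple(subset)
    if len(subset) == 0:
        raise DegenerateDataError("subset must be nonempty")
    missing = [s for s in subset if s not in X.columns]
    if missing:
        raise SchemaError(f"subset features not in the matrix: {missing}")
    n = len(X)
    if n < 6:
        raise DegenerateDataError(f"need at least 6 rows, got {n}")
    Xs = X.loc[:, list(subset)]
    if not train_only_norm:
        Xs_norm, _ = normalize(Xs)

    ss = np.random.SeedSequence(seed)
    split_seeds = ss.generate_state(R * (MAX_REDRAWS // 10 + 1)).tolist()
    bag_rng = np.random.default_rng(ss.spawn(1)[0])

    records = []
    seed_cursor = 0
    for r in range(R):
        for attempt in range(10):
            plan = split_train_test(n, int(split_seeds[seed_cursor] % 2**31))
            seed_cursor += 1
            if (np.unique(y[plan.train_indices]).size == 2
                    and np.unique(y[plan.test_indices]).size == 2):
                break
        else:
            raise DegenerateDataError(
                "could not obtain a two-class train/test split in 10 attempts")
        if train_only_norm:
            Xtr, params = normalize(Xs.iloc[plan.train_indices])
            Xte = (Xs.iloc[plan.test_indices] - params.mean) / params.sd
        else:
            Xtr = Xs_norm.iloc[plan.train_indices]
            Xte = Xs_norm.iloc[plan.test_indices]
        y_tr = y[plan.train_indices]
        y_te = y[plan.test_indices]
        ens = fit_bagged_ensemble(
            Xtr.reset_index(drop=True), y_tr, B=B,
            seed=int(bag_rng.integers(2**31)),
            penalties=class_penalties(y_tr))
        scores = (Xte.to_numpy(dtype=float) @ ens.aggregate.weights
                  + ens.aggregate.bias)
        preds = (scores >= 0).astype(int)
        m = prediction_measures(preds, y_te)
        m["prevalence"] = float(np.mean(y_te == 1))
        m["positive_rate"] = float(np.mean(preds == 1))
        m["repeat"] = r
        records.append(m)

    per_repeat = pd.DataFrame(records)
    summary, undefined, degenerate = _summarize(per_repeat, R)
    return EvaluationResult(summary=summary, per_repeat=per_repeat, R=R, B=B,
                            subset=subset, seed=seed, n_undefined=undefined,
                            degenerate_se=degenerate or R < 2)


def subset_size_curve(X: pd.DataFrame, y, ranking, B: int = 50, R: int = 100,
                      seed: int | None = None) -> pd.DataFrame:
    """Diagnostic measures versus subset size k.

    ``ranking`` is either an ordered feature list (first-k prefixes are
    evaluated) or a :class:`~sepsipanel.selection.SelectionTrace` (the best
    subset at each k is evaluated). Every k reuses the same seeded sequence
    of splits (a paired design), so differences across k are not confounded
    by split noise and each row is exactly a ``repeated_evaluation`` result.
    Returns a long table with columns k, measure, mean, se, R, B, seed.
    """
    from .selection import SelectionTrace

    if isinstance(ranking, SelectionTrace):
        subsets = [ranking.members_at(k) for k in range(1, len(ranking.member_sets) + 1)]
    else:
        ranking = list(ranking)
        subsets = [tuple(ranking[:k]) for k in range(1, len(ranking) + 1)]
    rows = []
    for k, subset in enumerate(subsets, start=1):
        res = repeated_evaluation(X, y, subset, B=B, R=R, seed=seed)
        for m in MEASURES:
            rows.append({"k": k, "measure": m, "mean": res.mean(m), "se": res.se(m),
                         "R": R, "B": B, "seed": seed})
    return pd.DataFrame(rows)
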