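"""Best-subset biomarker selection by canonical correlation with the outcome.

With a one-dimensional 0/1 severity score, the first canonical correlation
between a feature subset and the outcome reduces to the multiple correlation
coefficient: the square root of the R^2 of an ordinary least-squares fit of
the score on the subset (plus intercept). Exhaustive enumeration over all
C(p, k) subsets is tractable at p = 19 (2^19 - 1 ~ 5.2e5 subsets in total)
because each subset only requires solving a k x k normal-equation system
assembled from a single precomputed cross-product matrix; subsets of a given
size are solved as one batched call.

The stepwise trace mirrors the published selection table: row k lists the
best k-subset, which biomarkers entered relative to row k-1, and which left.
Greedy forward selection is provided for comparison; on suppressor
configurations it diverges from the exhaustive search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SchemaError

#: Relative singular-value threshold below which directions are treated as null.
RANK_RCOND = 1e-10


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, tuple(f"x{j}" for j in range(X.shape[1]))


class SubsetScorer:
    """Precomputed centered cross-products for fast subset R^2 evaluation."""

    def __init__(self, X, y):
        X, self.feature_names = _as_matrix(X)
        y = np.asarray(y, dtype=float)
        if len(y) != X.shape[0]:
            raise SchemaError("X and y lengths differ")
        if np.unique(y).size < 2:
            raise DegenerateDataError("outcome has a single distinct value")
        self.n, self.p = X.shape
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        self.C = Xc.T @ Xc          # p x p centered Gram matrix
        self.c = Xc.T @ yc          # p-vector of covariances with the outcome
        self.syy = float(yc @ yc)

    def r2(self, subset: tuple[int, ...]) -> float:
        """R^2 of the outcome on the subset; pseudo-inverse on rank deficiency."""
        idx = np.asarray(subset, dtype=int)
        A = self.C[np.ix_(idx, idx)]
        b = self.c[idx]
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(A, rcond=RANK_RCOND) @ b
        return float(np.clip(beta @ b / self.syy, 0.0, 1.0))

    def r2_batch(self, subsets: np.ndarray) -> np.ndarray:
        """R^2 for an (m, k) array of index subsets, solved in one batch."""
        A = self.C[subsets[:, :, None], subsets[:, None, :]]
        b = self.c[subsets]
        try:
            beta = np.linalg.solve(A, b[..., None])[..., 0]
            r2 = np.einsum("mk,mk->m", beta, b) / self.syy
        except np.linalg.LinAlgError:
            r2 = np.array([self.r2(tuple(s)) for s in subsets])
        return np.clip(r2, 0.0, 1.0)


def canonical_correlation(X_S, y) -> float:
    """First canonical correlation between a feature subset and a 0/1 outcome.

    Equals the multiple correlation coefficient sqrt(R^2) of the least-squares
    regression of ``y`` on ``X_S`` with intercept. Rank-deficient subsets are
    handled by pseudo-inverse, yielding the supremum correlation over the
    column space.
    """
    Xm, _ = _as_matrix(X_S)
    n, k = Xm.shape
    if k == 0:
        raise DegenerateDataError("empty feature subset")
    if n <= k:
        raise DegenerateDataError(
            f"underdetermined: n={n} samples for a subset of size {k}")
    scorer = SubsetScorer(Xm, y)
    return float(np.sqrt(scorer.r2(tuple(range(k)))))


@dataclass
class SelectionTrace:
    """Stepwise best-subset table: one row per subset size k.

    ``frame`` columns: dim, corr, entering, leaving, members (name lists
    joined by ", "; ordered by feature index).
    """

    frame: pd.DataFrame
    member_sets: list[tuple[str, ...]]

    def members_at(self, k: int) -> tuple[str, ...]:
        return self.member_sets[k - 1]

    def correlations(self) -> np.ndarray:
        return self.frame["corr"].to_numpy()

    def first_entry_dim(self, feature: str) -> int | None:
        """Smallest k at which ``feature`` is in the best subset (None if never)."""
        for k, members in enumerate(self.member_sets, start=1):
            if feature in members:
                return k
        return None

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.frame.to_csv(fh, sep="\t", index=False)


def _check_k(k: int, p: int) -> None:
    if not 1 <= k <= p:
        raise DegenerateDataError(f"subset size k={k} out of range 1..{p}")


def best_subset_of_size(X, y, k: int) -> tuple[tuple[str, ...], float]:
    """Exhaustively maximize the canonical correlation over all k-subsets.

    Ties are broken in favour of the lexicographically smallest feature-index
    set. Returns the winning feature names and the correlation.
    """
    Xm, names = _as_matrix(X)
    _check_k(k, Xm.shape[1])
    if Xm.shape[0] <= k:
        raise DegenerateDataError(f"underdetermined: n={Xm.shape[0]}, k={k}")
    scorer = SubsetScorer(Xm, y)
    subset, corr = _best_of_size(scorer, k)
    return tuple(names[j] for j in subset), corr


def _best_of_size(scorer: SubsetScorer, k: int) -> tuple[tuple[int, ...], float]:
    subsets = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(scorer.p), k)),
        dtype=np.intp).reshape(-1, k)
    r2 = scorer.r2_batch(subsets)
    best = int(np.argmax(r2))  # first maximum = lexicographically smallest set
    return tuple(int(j) for j in subsets[best]), float(np.sqrt(r2[best]))


def stepwise_trace(X, y, k_max: int) -> SelectionTrace:
    """Best-subset trace for k = 1..k_max with entering/leaving bookkeeping."""
    Xm, names = _as_matrix(X)
    _check_k(k_max, Xm.shape[1])
    if Xm.shape[0] <= k_max:
        raise DegenerateDataError(f"underdetermined: n={Xm.shape[0]}, k_max={k_max}")
    scorer = SubsetScorer(Xm, y)
    rows = []
    member_sets: list[tuple[str, ...]] = []
    prev: set[int] = set()
    for k in range(1, k_max + 1):
        subset, corr = _best_of_size(scorer, k)
        cur = set(subset)
        entering = sorted(cur - prev)
        leaving = sorted(prev - cur)
        rows.append({
            "dim": k,
            "corr": corr,
            "entering": ", ".join(names[j] for j in entering),
            "leaving": ", ".join(names[j] for j in leaving),
            "members": ", ".join(names[j] for j in sorted(cur)),
        })
        member_sets.append(tuple(names[j] for j in sorted(cur)))
        prev = cur
    return SelectionTrace(pd.DataFrame(rows), member_sets)


def forward_selection(X, y, k_max: int) -> list[str]:
    """Greedy forward selection: add the single best feature at each step.

    Never removes a feature; ties broken by smallest feature index. Returns
    the ordered list of selected feature names.
    """
    Xm, names = _as_matrix(X)
    _check_k(k_max, Xm.shape[1])
    if Xm.shape[0] <= k_max:
        raise DegenerateDataError(f"underdetermined: n={Xm.shape[0]}, k_max={k_max}")
    scorer = SubsetScorer(Xm, y)
    selected: list[int] = []
    remaining = list(range(scorer.p))
    for _ in range(k_max):
        best_j, best_r2 = -1, -np.inf
        for j in remaining:
            r2 = scorer.r2(tuple(selected + [j]))
            if r2 > best_r2 + 0.0:  # strict improvement keeps smallest index on ties
                best_j, best_r2 = j, r2
        selected.append(best_j)
        remaining.remove(best_j)
    return [names[j] for j in selected]
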