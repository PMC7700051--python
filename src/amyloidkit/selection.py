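"""Feature ranking and selection.

Two rankers are provided, each matched to one feature block:

* **MRMD** (max relevance, max distance) for the 188-dim CTD block: each
  feature's score is the sum of its relevance (|Pearson correlation| with
  the class labels) and its mean distance to the other feature columns
  (Euclidean, 1 - cosine similarity, 1 - Tanimoto coefficient, or the mean
  of the three).  Relevance and distance are min-max normalized across
  features before summing, since raw distances are unbounded while |PCC|
  lives in [0, 1].

* **Binomial-distribution (BD) confidence** for the 8000-dim tripeptide
  block: for each tripeptide the upper-tail binomial probability of its
  class-specific occurrence count under the class's overall occurrence
  share, converted to a confidence level CL = 1 - P; the larger of the two
  per-class CL values ranks the feature.

Both produce a deterministic descending-score order with ties broken by
ascending feature index, consumed by the incremental ranked-subset
evaluation loop (nested subsets D_1 c D_2 c ... scored by stratified
cross-validation accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import binom
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

MRMD_METRICS = ("ED", "COS", "TC", "MEAN")


@dataclass(frozen=True)
class RankedFeatures:
    """Per-feature scores plus the deterministic descending-score order."""

    scores: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "order", np.asarray(self.order, dtype=np.int64))
        if self.scores.shape != self.order.shape:
            raise ValueError("scores and order must have equal length")

    def top(self, k: int) -> np.ndarray:
        """Indices of the k best features, in rank order."""
        return self.order[:k]


def _rank_order(keys: np.ndarray) -> np.ndarray:
    """Ascending-key stable argsort (ties by original index)."""
    return np.argsort(keys, kind="stable")


def pearson_relevance(X: np.ndarray, y: np.ndarray, feature_index: int) -> float:
    """|Pearson correlation| between one feature column and the labels.

    Returns 0 when either the column or the labels have zero variance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    col = X[:, feature_index]
    if col.std() == 0 or y.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(col, y)[0, 1]))


def _pairwise_distances(X: np.ndarray, metric: str) -> np.ndarray:
    """d x d distance matrix between feature COLUMN vectors."""
    cols = np.asarray(X, dtype=float).T  # (d, n)
    d = cols.shape[0]
    if metric == "ED":
        return squareform(pdist(cols, metric="euclidean"))
    dots = cols @ cols.T
    sq = np.diag(dots)
    if metric == "COS":
        norms = np.sqrt(sq)
        denom = np.outer(norms, norms)
        with np.errstate(divide="ignore", invalid="ignore"):
            sim = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 1.0)
        # a zero-norm column makes the pair contribute 0 distance
        dist = 1.0 - np.clip(sim, -1.0, 1.0)
    elif metric == "TC":
        denom = sq[:, None] + sq[None, :] - dots
        with np.errstate(divide="ignore", invalid="ignore"):
            sim = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 1.0)
        zero = (sq[:, None] == 0) | (sq[None, :] == 0)
        sim = np.where(zero, 1.0, sim)  # zero-norm pair contributes 0 distance
        dist = 1.0 - sim
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(dist, 0.0)
    return np.maximum(dist, 0.0)


def feature_distance(
    X: np.ndarray, feature_index: int, metric: str = "ED"
) -> float:
    """Mean distance from one feature column to all other feature columns.

    Larger means less redundant.  ``metric`` is ED (Euclidean),
    COS (1 - cosine similarity) or TC (1 - Tanimoto coefficient).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    dist = _pairwise_distances(X, metric)
    row = np.delete(dist[feature_index], feature_index)
    return float(row.mean())


def _md_scores(X: np.ndarray, metric: str) -> np.ndarray:
    d = X.shape[1]
    if metric == "MEAN":
        comps = [_pairwise_distances(X, m) for m in ("ED", "COS", "TC")]
        dist = sum(comps) / 3.0
    else:
        dist = _pairwise_distances(X, metric)
    return dist.sum(axis=1) / (d - 1)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def mrmd_rank(X: np.ndarray, y: np.ndarray, metric: str = "ED") -> RankedFeatures:
    """Rank features by normalized relevance + normalized mean distance.

    Parameters
    ----------
    X : (n, d) array
        Feature matrix; needs n >= 2 samples, d >= 2 features and both
        classes present in ``y``.
    metric : {"ED", "COS", "TC", "MEAN"}
        Distance function for the redundancy term; MEAN averages the three.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if metric not in MRMD_METRICS:
        raise ValueError(f"metric must be one of {MRMD_METRICS}, got {metric!r}")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("MRMD needs at least 2 samples and 2 features")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if (X.std(axis=0) == 0).all():
        raise ValueError("all features are constant; no ranking possible")
    mr = np.array([pearson_relevance(X, y, i) for i in range(X.shape[1])])
    md = _md_scores(X, metric)
    scores = _minmax(mr) + _minmax(md)
    order = _rank_order(-scores)
    return RankedFeatures(scores=scores, order=order)


def binomial_tail(N_i: int, n_ij: int, q_j: float) -> float:
    """Upper-tail binomial probability P(X >= n_ij) for X ~ Bin(N_i, q_j).

    Computed with scipy's survival function, which is numerically stable
    for the tiny tail probabilities strongly enriched tripeptides produce.
    """
    if N_i < 1 or not 0 <= n_ij <= N_i:
        raise ValueError(f"need 0 <= n_ij <= N_i with N_i >= 1, got N_i={N_i}, n_ij={n_ij}")
    if not 0 < q_j < 1:
        raise ValueError(f"q_j must be in (0, 1), got {q_j}")
    if n_ij == 0:
        return 1.0
    return float(binom.sf(n_ij - 1, N_i, q_j))


def bd_rank(counts: np.ndarray, y: np.ndarray) -> RankedFeatures:
    """Rank tripeptide features by binomial-distribution confidence level.

    Parameters
    ----------
    counts : (n, d) array of occurrence COUNTS
        Raw per-sample tripeptide occurrence counts (not frequencies).
    y : (n,) binary labels

    For each tripeptide i: N_i = total occurrences, n_ij = occurrences in
    class j, q_j = class j's share of all tripeptide occurrences;
    CL_i = max_j (1 - P_ij) where P_ij is the upper binomial tail.
    Tripeptides absent from every sample get CL 0 and rank last.  Order is
    by P ascending (equivalently CL descending, without the float precision
    loss of 1 - P near 1), ties by feature index.
    """
    counts = np.asarray(counts, dtype=float)
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if counts.min() < 0 or not np.allclose(counts, np.round(counts)):
        raise ValueError("bd_rank expects non-negative integer occurrence counts")
    per_class = np.vstack([counts[y == j].sum(axis=0) for j in (0, 1)])  # (2, d)
    totals = per_class.sum(axis=0)  # N_i
    class_totals = per_class.sum(axis=1)
    grand = class_totals.sum()
    if (class_totals == 0).any():
        raise ValueError("a class has zero total tripeptide occurrences")
    q = class_totals / grand
    d = counts.shape[1]
    pmin = np.ones(d)
    nonzero = totals > 0
    for j in (0, 1):
        n_ij = per_class[j, nonzero]
        p = np.ones(n_ij.size)
        pos = n_ij > 0
        p[pos] = binom.sf(n_ij[pos] - 1, totals[nonzero][pos], q[j])
        sub = pmin[nonzero]
        pmin[nonzero] = np.minimum(sub, p)
    cl = np.where(nonzero, 1.0 - pmin, 0.0)
    # absent features (N_i = 0) sort after everything: give them key > 1
    keys = np.where(nonzero, pmin, 2.0)
    order = _rank_order(keys)
    return RankedFeatures(scores=cl, order=order)


@dataclass(frozen=True)
class SubsetEvaluation:
    """Cross-validation accuracy of the top-k ranked-feature subset."""

    k: int
    accuracy: float


@dataclass
class SubsetCurve:
    """Accuracy curve over nested ranked subsets, with the selection summary."""

    evaluations: list[SubsetEvaluation]
    tolerance: float
    best_k: int = field(init=False)
    best_accuracy: float = field(init=False)
    selected_k: int = field(init=False)

    def __post_init__(self) -> None:
        accs = np.array([e.accuracy for e in self.evaluations])
        ks = np.array([e.k for e in self.evaluations])
        best = int(np.argmax(accs))  # first max -> smallest k on ties
        self.best_k = int(ks[best])
        self.best_accuracy = float(accs[best])
        ok = np.flatnonzero(accs >= self.best_accuracy - self.tolerance)
        self.selected_k = int(ks[ok[0]])


def incremental_subset_eval(
    X: np.ndarray,
    y: np.ndarray,
    ranking: RankedFeatures,
    k_max: int,
    evaluator=None,
    folds: int = 10,
    seed: int = 0,
    tolerance: float = 0.0,
) -> SubsetCurve:
    """Score nested top-k feature subsets by stratified k-fold CV accuracy.

    For k = 1..k_max the subset is the top k features of ``ranking``; each
    is scored with a fresh clone of ``evaluator`` (default: support-vector
    classifier with default hyperparameters) under a seed-fixed stratified
    fold split shared across all k.  The returned curve also records the
    argmax-k and the smallest k whose accuracy is within ``tolerance`` of
    the maximum (the parsimony choice).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    if not 1 <= k_max <= d:
        raise ValueError(f"k_max must be in [1, {d}]")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if evaluator is None:
        evaluator = SVC()
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    evaluations = []
    for k in range(1, k_max + 1):
        cols = ranking.top(k)
        try:
            accs = cross_val_score(
                clone(evaluator), X[:, cols], y, cv=cv, scoring="accuracy"
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"evaluator failed on subset k={k}") from exc
        evaluations.append(SubsetEvaluation(k=k, accuracy=float(np.mean(accs))))
    return SubsetCurve(evaluations=evaluations, tolerance=tolerance)


class _RankedSelector(SelectorMixin, BaseEstimator):
    """Shared fit/support plumbing for the two ranking selectors."""

    def __init__(self, k: int = 10):
        self.k = k

    def _rank(self, X, y) -> RankedFeatures:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y):
        X = validate_data(self, X, ensure_2d=True, dtype=float, reset=True)
        y = np.asarray(y)
        if not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k must be in [1, {X.shape[1]}], got {self.k}")
        self.ranking_ = self._rank(X, y)
        self.scores_ = self.ranking_.scores
        self.selected_indices_ = np.sort(self.ranking_.top(self.k))
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "selected_indices_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_indices_] = True
        return mask


class MRMDSelector(_RankedSelector):
    """Select the top-k features of the MRMD ranking.

    Parameters
    ----------
    k : int
        Number of features to keep (default 121, the size used for the
        CTD block in the reference pipeline).
    metric : {"ED", "COS", "TC", "MEAN"}
        Distance function for the redundancy term (default ED).
    """

    def __init__(self, k: int = 121, metric: str = "ED"):
        super().__init__(k=k)
        self.metric = metric

    def _rank(self, X, y) -> RankedFeatures:
        return mrmd_rank(X, y, metric=self.metric)


class BinomialSelector(_RankedSelector):
    """Select the top-k tripeptides of the binomial-confidence ranking.

    ``fit`` expects raw occurrence counts (e.g. from
    ``TripeptideEncoder(output="count")``); ``transform`` can then be applied
    to counts or to the matching frequency matrix, since selection is purely
    columnar.  Default k = 425, the TPC subset size of the reference
    pipeline.
    """

    def __init__(self, k: int = 425):
        super().__init__(k=k)

    def _rank(self, X, y) -> RankedFeatures:
        return bd_rank(X, y)
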