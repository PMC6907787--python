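"""Random-forest classification of samples to treatment, written in-repo.

Trees are CART classifiers grown on bootstrap resamples: at every node
``mtry`` features are sampled without replacement and the split minimizing
the weighted Gini impurity of the children is taken, with numeric thresholds
at midpoints of consecutive sorted unique values.  Growth stops at purity or
at the minimum node size (default 1, no depth limit).  Per-tree bootstrap
membership is recorded so out-of-bag (OOB) votes, the OOB confusion matrix
and the OOB error rate can be computed, and every split contributes
node-size-weighted impurity decrease to the mean-decrease-Gini importance of
its feature.

The feature-count tuning mirrors the iterative workflow: for each candidate
count m = 1..M a forest is fitted ``reps`` times with mtry = m under fresh
derived seeds, and the m attaining the minimum median OOB error is chosen
(ties to the smaller m); per-m means are reported alongside the medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ._rng import substream
from .errors import ConfigError, DataError

__all__ = [
    "Forest",
    "TuneResult",
    "grow_tree",
    "fit_forest",
    "oob_summary",
    "OobSummary",
    "gini_importance",
    "tune_feature_count",
]

_LEAF = -1


@njit(cache=False)
def _gini(counts, total):
    if total <= 0:
        return 0.0
    g = 1.0
    for c in range(counts.shape[0]):
        p = counts[c] / total
        g -= p * p
    return g


@njit(cache=False)
def _grow(X, y, n_classes, idx, mtry, min_node, seed,
          feature, threshold, left, right, leaf_class, importance):
    """Grow one tree over bootstrap positions ``idx`` (with repeats).

    Node arrays are filled in place; returns the number of nodes used.
    """
    np.random.seed(seed)
    n_feat = X.shape[1]
    perm = np.arange(n_feat)
    n_total = idx.shape[0]

    # explicit stack of (node, start, end) ranges into idx
    stack_node = np.empty(4 * n_total + 4, dtype=np.int64)
    stack_lo = np.empty(4 * n_total + 4, dtype=np.int64)
    stack_hi = np.empty(4 * n_total + 4, dtype=np.int64)
    top = 0
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n_total
    n_nodes = 1

    counts = np.empty(n_classes, dtype=np.int64)
    left_counts = np.empty(n_classes, dtype=np.int64)
    buf = np.empty(n_total, dtype=np.int64)

    while top >= 0:
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        top -= 1
        m = hi - lo

        counts[:] = 0
        for i in range(lo, hi):
            counts[y[idx[i]]] += 1
        majority = 0
        for c in range(1, n_classes):
            if counts[c] > counts[majority]:
                majority = c
        pure = counts[majority] == m

        if pure or m <= min_node:
            feature[node] = _LEAF
            leaf_class[node] = majority
            continue

        parent_gini = _gini(counts, m)
        best_score = np.inf
        best_feat = -1
        best_thr = 0.0

        # sample mtry distinct features (partial Fisher-Yates)
        for i in range(mtry):
            j = i + np.random.randint(0, n_feat - i)
            tmp = perm[i]
            perm[i] = perm[j]
            perm[j] = tmp

        vals = np.empty(m)
        for fi in range(mtry):
            f = perm[fi]
            for i in range(m):
                vals[i] = X[idx[lo + i], f]
            order = np.argsort(vals[:m], kind="mergesort")
            left_counts[:] = 0
            nl = 0
            for k in range(m - 1):
                row = idx[lo + order[k]]
                left_counts[y[row]] += 1
                nl += 1
                v_k = vals[order[k]]
                v_next = vals[order[k + 1]]
                if v_next > v_k:
                    nr = m - nl
                    score = (
                        nl * _gini(left_counts, nl)
                        + nr * _gini(counts - left_counts, nr)
                    ) / m
                    if score < best_score - 1e-12:
                        best_score = score
                        best_feat = f
                        best_thr = 0.5 * (v_k + v_next)

        if best_feat < 0:  # all sampled features constant on this node
            feature[node] = _LEAF
            leaf_class[node] = majority
            continue

        importance[best_feat] += m * (parent_gini - best_score)

        # stable partition of idx[lo:hi] on the chosen split
        n_left = 0
        n_right = 0
        for i in range(lo, hi):
            if X[idx[i], best_feat] <= best_thr:
                buf[n_left] = idx[i]
                n_left += 1
        for i in range(lo, hi):
            if X[idx[i], best_feat] > best_thr:
                buf[n_left + n_right] = idx[i]
                n_right += 1
        for i in range(m):
            idx[lo + i] = buf[i]

        feature[node] = best_feat
        threshold[node] = best_thr
        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        left[node] = lchild
        right[node] = rchild
        top += 1
        stack_node[top] = lchild
        stack_lo[top] = lo
        stack_hi[top] = lo + n_left
        top += 1
        stack_node[top] = rchild
        stack_lo[top] = lo + n_left
        stack_hi[top] = hi
    return n_nodes


@njit(cache=False)
def _predict_rows(X, rows, feature, threshold, left, right, leaf_class, out):
    for r in range(rows.shape[0]):
        node = 0
        while feature[node] != _LEAF:
            if X[rows[r], feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[r] = leaf_class[node]


@dataclass
class _Tree:
    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_class: np.ndarray

    def predict(self, X: np.ndarray, rows: np.ndarray) -> np.ndarray:
        out = np.empty(len(rows), dtype=np.int64)
        _predict_rows(X, rows, self.feature, self.threshold,
                      self.left, self.right, self.leaf_class, out)
        return out


def grow_tree(X, y_codes, in_bag, n_classes, mtry, min_node=1, seed=0):
    """Grow a single tree; ``in_bag`` is the bootstrap index multiset.

    Returns ``(tree, importance)`` with importance the per-feature sum of
    node-size-weighted Gini decreases.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    idx = np.asarray(in_bag, dtype=np.int64).copy()
    if idx.size == 0:
        raise DataError("empty in-bag multiset")
    if mtry < 1 or mtry > X.shape[1]:
        raise ConfigError("mtry must lie in [1, n_features]")
    cap = 2 * idx.size + 1
    feature = np.full(cap, _LEAF, dtype=np.int64)
    threshold = np.zeros(cap)
    left = np.zeros(cap, dtype=np.int64)
    right = np.zeros(cap, dtype=np.int64)
    leaf_class = np.zeros(cap, dtype=np.int64)
    importance = np.zeros(X.shape[1])
    n_nodes = _grow(
        X, np.asarray(y_codes, dtype=np.int64), n_classes, idx,
        int(mtry), int(min_node), int(seed),
        feature, threshold, left, right, leaf_class, importance,
    )
    tree = _Tree(feature[:n_nodes], threshold[:n_nodes], left[:n_nodes],
                 right[:n_nodes], leaf_class[:n_nodes])
    return tree, importance


@dataclass
class Forest:
    """A fitted forest with bootstrap bookkeeping."""

    trees: list
    classes_: np.ndarray
    in_bag: np.ndarray  # n_trees x n bootstrap multiplicities
    oob_votes: np.ndarray  # n x n_classes
    importance_sum: np.ndarray
    n_trees: int
    mtry: int
    seed: int
    tie_perm: np.ndarray  # seeded class order for vote tie-breaking
    X: np.ndarray


def fit_forest(X, y, n_trees: int = 2000, mtry: int | None = None,
               min_node: int = 1, seed: int = 0) -> Forest:
    """Fit a random forest (bootstrap per tree, OOB votes accumulated)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise DataError("need at least two classes")
    n, f = X.shape
    if mtry is None:
        mtry = max(1, int(np.floor(np.sqrt(f))))
    if mtry > f:
        raise ConfigError("mtry exceeds the number of features")

    rng = substream(seed, "forest")
    boot = rng.integers(0, n, size=(n_trees, n))
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees)
    tie_perm = rng.permutation(len(classes))

    in_bag = np.zeros((n_trees, n), dtype=np.int16)
    oob_votes = np.zeros((n, len(classes)), dtype=np.int64)
    importance_sum = np.zeros(f)
    trees = []
    for t in range(n_trees):
        counts = np.bincount(boot[t], minlength=n)
        in_bag[t] = counts
        tree, imp = grow_tree(X, y_codes, boot[t], len(classes),
                              mtry, min_node, int(tree_seeds[t]))
        importance_sum += imp
        oob_rows = np.flatnonzero(counts == 0)
        if oob_rows.size:
            pred = tree.predict(X, oob_rows)
            for r, c in zip(oob_rows, pred):
                oob_votes[r, c] += 1
        trees.append(tree)
    return Forest(trees=trees, classes_=classes, in_bag=in_bag,
                  oob_votes=oob_votes, importance_sum=importance_sum,
                  n_trees=n_trees, mtry=mtry, seed=seed, tie_perm=tie_perm, X=X)


@dataclass
class OobSummary:
    error: float
    per_class_error: pd.Series
    confusion: pd.DataFrame  # true rows x predicted columns
    predicted: pd.Series  # per-sample OOB label (NaN if never OOB)
    unclassified: list


def oob_summary(forest: Forest, y) -> OobSummary:
    """OOB error, per-class error and confusion matrix (true x predicted).

    Predicted label is the plurality of OOB votes; ties go to the class
    earliest in the forest's seeded class shuffle.  Samples never out of bag
    are reported as unclassified and excluded from the error.
    """
    y = np.asarray(y)
    classes = forest.classes_
    votes = forest.oob_votes
    n = votes.shape[0]
    pred = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if votes[i].sum() == 0:
            continue
        best = votes[i].max()
        tied = np.flatnonzero(votes[i] == best)
        if len(tied) == 1:
            pred[i] = tied[0]
        else:
            ranks = {c: r for r, c in enumerate(forest.tie_perm)}
            pred[i] = min(tied, key=lambda c: ranks[c])
    class_index = {c: j for j, c in enumerate(classes)}
    true_codes = np.array([class_index[v] for v in y])

    confusion = pd.DataFrame(0, index=classes, columns=classes)
    unclassified = []
    for i in range(n):
        if pred[i] < 0:
            unclassified.append(i)
            continue
        confusion.iloc[true_codes[i], pred[i]] += 1
    classified = confusion.to_numpy().sum()
    errors = classified - np.trace(confusion.to_numpy())
    per_class = pd.Series(
        {
            c: (1.0 - confusion.loc[c, c] / confusion.loc[c].sum())
            if confusion.loc[c].sum() > 0
            else np.nan
            for c in classes
        }
    )
    predicted = pd.Series(
        [classes[p] if p >= 0 else np.nan for p in pred], index=range(n)
    )
    return OobSummary(
        error=errors / classified if classified else np.nan,
        per_class_error=per_class,
        confusion=confusion,
        predicted=predicted,
        unclassified=unclassified,
    )


def gini_importance(forest: Forest, feature_names=None) -> pd.Series:
    """Mean decrease in Gini per feature, sorted descending.

    Per feature: the sum over all splits using it of node size x impurity
    decrease, averaged over trees.  Nonnegative by construction; features
    never used in a split score exactly 0.
    """
    imp = forest.importance_sum / forest.n_trees
    if feature_names is None:
        feature_names = [f"feature{j}" for j in range(len(imp))]
    s = pd.Series(imp, index=feature_names)
    return s.sort_values(ascending=False, kind="stable")


@dataclass
class TuneResult:
    errors: pd.DataFrame  # M x reps OOB errors
    medians: pd.Series
    means: pd.Series
    chosen_m: int


def tune_feature_count(X, y, M: int = 100, reps: int = 100,
                       n_trees: int = 2000, seed: int = 0,
                       min_node: int = 1) -> TuneResult:
    """Choose the per-split feature count by minimum median OOB error.

    For each m = 1..M, ``reps`` forests are fitted with mtry = m under seeds
    derived from the master seed; the chosen m attains the minimum median
    OOB error, ties broken toward smaller m.  The per-m mean OOB error is
    reported alongside.
    """
    if M < 1:
        raise ConfigError("M must be >= 1")
    X = np.ascontiguousarray(X, dtype=np.float64)
    if M > X.shape[1]:
        raise ConfigError("M exceeds the number of features")
    seeds = substream(seed, "tune").integers(0, 2**31 - 1, size=(M, reps))
    errors = np.empty((M, reps))
    for mi in range(M):
        for r in range(reps):
            forest = fit_forest(X, y, n_trees=n_trees, mtry=mi + 1,
                                min_node=min_node, seed=int(seeds[mi, r]))
            errors[mi, r] = oob_summary(forest, y).error
    frame = pd.DataFrame(errors, index=pd.Index(range(1, M + 1), name="m"))
    medians = frame.median(axis=1)
    chosen = int(medians.idxmin())  # idxmin takes the first (smallest m) on ties
    return TuneResult(errors=frame, medians=medians,
                      means=frame.mean(axis=1), chosen_m=chosen)
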