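"""Random forest with Gini mean-decrease-in-impurity, built from scratch.

The forest is the feature-ranking engine of the pipeline: each tree is grown
on a bootstrap sample with a fresh uniform subsample of candidate features at
every split, the best split maximizes the Gini impurity decrease

    dI_n = I(N_n) - (N_L / N_n) I(N_L) - (N_R / N_n) I(N_R),
    I(N)  = 1 - sum_k p_k^2,

and a feature's importance is the average over trees of the sample-weighted
impurity decrease summed over the nodes that split on it (MDI), normalized to
sum to one. Recursive feature elimination repeatedly drops the lowest-MDI
feature while tracking stratified 10-fold cross-validated accuracy; the
subset with the highest mean accuracy wins (ties go to fewer features).

Tree growing and prediction are numba-compiled; everything else is plain
numpy. Determinism: per-tree seeds derive from the forest seed, split ties
break towards the lowest feature index and lowest threshold, prediction ties
towards the lowest class index, and MDI ties in the elimination loop drop
the feature latest in the canonical order (ra, rt, ptm, lft, rlt, not, rot).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .metrics import FEATURE_ORDER

__all__ = [
    "LabeledTable",
    "ForestConfig",
    "RandomForest",
    "ImportanceTrace",
    "RfeIteration",
    "gini",
    "impurity_decrease",
    "train_forest",
    "mdi",
    "cv_accuracy",
    "rfe",
]

CANONICAL_ORDER = FEATURE_ORDER


def gini(counts: Sequence[float]) -> float:
    """Gini impurity ``1 - sum p_k^2`` of a per-class count vector."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be > 0")
    p = counts / total
    return float(1.0 - (p * p).sum())


def impurity_decrease(parent_counts, left_counts, right_counts) -> float:
    """Gini decrease of splitting ``parent`` into ``left`` + ``right``."""
    parent = np.asarray(parent_counts, dtype=float)
    left = np.asarray(left_counts, dtype=float)
    right = np.asarray(right_counts, dtype=float)
    if not np.array_equal(left + right, parent):
        raise ValueError("left + right must equal parent elementwise")
    n = parent.sum()
    nl, nr = left.sum(), right.sum()
    if nl <= 0 or nr <= 0:
        raise ValueError("both children must be non-empty")
    return gini(parent) - (nl / n) * gini(left) - (nr / n) * gini(right)


@dataclass
class LabeledTable:
    """Feature matrix + class labels for supervised strategy prediction."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y length mismatch")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")
        self.feature_names = tuple(self.feature_names)

    @classmethod
    def from_features_and_labels(
        cls,
        features: pd.DataFrame,
        labels: pd.DataFrame,
        feature_names: Sequence[str] = CANONICAL_ORDER,
        classes: int = 2,
    ) -> "LabeledTable":
        """Join a feature table with strategy labels.

        ``classes=2`` keeps only CM/RE trials (the two-strategy analysis);
        ``classes=3`` keeps CM/RE/IE.
        """
        keep = {"CM", "RE"} if classes == 2 else {"CM", "RE", "IE"}
        merged = features.merge(
            labels[["participant_id", "item_id", "label"]],
            on=["participant_id", "item_id"],
        )
        merged = merged[merged["label"].isin(keep)]
        X = merged[list(feature_names)].to_numpy(dtype=float)
        return cls(X=X, y=merged["label"].to_numpy(), feature_names=tuple(feature_names))


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    max_features: int | None = None  # default ceil(sqrt(k))
    bootstrap_size: int | None = None  # default n
    bootstrap: bool = True
    max_depth: int | None = None
    min_samples_split: int = 2
    seed: int = 0

    def validate(self, n: int, k: int) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        mf = self.resolved_max_features(k)
        if not 1 <= mf <= k:
            raise ValueError("max_features must be in [1, k]")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.bootstrap_size is not None and self.bootstrap_size < 1:
            raise ValueError("bootstrap_size must be >= 1")

    def resolved_max_features(self, k: int) -> int:
        return self.max_features if self.max_features is not None else math.ceil(math.sqrt(k))


@njit(cache=True)
def _fit_tree(X, y, n_classes, m, max_features, max_depth, min_samples_split,
              seed, use_bootstrap):
    np.random.seed(seed)
    n_total, k = X.shape
    if use_bootstrap:
        idx = np.random.randint(0, n_total, m)
    else:
        idx = np.arange(n_total)
        m = n_total
    cap = 2 * m + 1
    feat = np.full(cap, -1, np.int64)
    thr = np.zeros(cap, np.float64)
    left = np.full(cap, -1, np.int64)
    right = np.full(cap, -1, np.int64)
    leaf = np.full(cap, -1, np.int64)
    importance = np.zeros(k, np.float64)
    st_start = np.empty(cap, np.int64)
    st_end = np.empty(cap, np.int64)
    st_depth = np.empty(cap, np.int64)
    st_node = np.empty(cap, np.int64)
    st_start[0] = 0
    st_end[0] = m
    st_depth[0] = 0
    st_node[0] = 0
    top = 1
    n_nodes = 1
    featbuf = np.arange(k)
    counts = np.zeros(n_classes, np.int64)
    left_counts = np.zeros(n_classes, np.int64)
    tmp = np.empty(m, np.int64)
    while top > 0:
        top -= 1
        start = st_start[top]
        end = st_end[top]
        depth = st_depth[top]
        node = st_node[top]
        n_node = end - start
        for c in range(n_classes):
            counts[c] = 0
        for s in range(start, end):
            counts[y[idx[s]]] += 1
        imp = 1.0
        for c in range(n_classes):
            p = counts[c] / n_node
            imp -= p * p
        make_leaf = (
            imp <= 0.0
            or n_node < min_samples_split
            or (max_depth >= 0 and depth >= max_depth)
        )
        best_dec = 0.0
        best_f = -1
        best_thr = 0.0
        if not make_leaf:
            for a in range(max_features):
                j = np.random.randint(a, k)
                t = featbuf[a]
                featbuf[a] = featbuf[j]
                featbuf[j] = t
            chosen = np.sort(featbuf[:max_features])
            for fi in range(max_features):
                f = chosen[fi]
                vals = np.empty(n_node, np.float64)
                for s in range(n_node):
                    vals[s] = X[idx[start + s], f]
                order = np.argsort(vals)
                for c in range(n_classes):
                    left_counts[c] = 0
                for pos in range(n_node - 1):
                    left_counts[y[idx[start + order[pos]]]] += 1
                    v0 = vals[order[pos]]
                    v1 = vals[order[pos + 1]]
                    if v1 > v0:
                        nl = pos + 1
                        nr = n_node - nl
                        gl = 1.0
                        gr = 1.0
                        for cc in range(n_classes):
                            pl = left_counts[cc] / nl
                            pr = (counts[cc] - left_counts[cc]) / nr
                            gl -= pl * pl
                            gr -= pr * pr
                        dec = imp - (nl / n_node) * gl - (nr / n_node) * gr
                        if dec > best_dec:
                            th = 0.5 * (v0 + v1)
                            if th >= v1:  # guard against midpoint rounding up
                                th = v0
                            best_dec = dec
                            best_f = f
                            best_thr = th
            if best_f < 0 or best_dec <= 0.0:
                make_leaf = True
        if make_leaf:
            best_c = 0
            bc = counts[0]
            for c in range(1, n_classes):
                if counts[c] > bc:
                    bc = counts[c]
                    best_c = c
            leaf[node] = best_c
        else:
            importance[best_f] += (n_node / m) * best_dec
            feat[node] = best_f
            thr[node] = best_thr
            p = 0
            for s in range(start, end):
                if X[idx[s], best_f] <= best_thr:
                    tmp[p] = idx[s]
                    p += 1
            nl = p
            for s in range(start, end):
                if X[idx[s], best_f] > best_thr:
                    tmp[p] = idx[s]
                    p += 1
            for s in range(n_node):
                idx[start + s] = tmp[s]
            lnode = n_nodes
            rnode = n_nodes + 1
            n_nodes += 2
            left[node] = lnode
            right[node] = rnode
            st_start[top] = start
            st_end[top] = start + nl
            st_depth[top] = depth + 1
            st_node[top] = lnode
            top += 1
            st_start[top] = start + nl
            st_end[top] = end
            st_depth[top] = depth + 1
            st_node[top] = rnode
            top += 1
    return (
        feat[:n_nodes],
        thr[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        leaf[:n_nodes],
        importance,
    )


@njit(cache=True)
def _tree_votes(feat, thr, left, right, leaf, X, votes):
    for i in range(X.shape[0]):
        node = 0
        while leaf[node] < 0:
            if X[i, feat[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        votes[i, leaf[node]] += 1


class RandomForest:
    """Bagged Gini decision trees with majority-vote prediction."""

    def __init__(self, config: ForestConfig):
        self.config = config
        self.trees_: list[tuple] = []
        self.classes_: np.ndarray | None = None
        self.tree_importances_: np.ndarray | None = None
        self.feature_names_: tuple[str, ...] | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, feature_names=None) -> "RandomForest":
        X = np.ascontiguousarray(X, dtype=np.float64)
        classes, y_enc = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        n, k = X.shape
        self.config.validate(n, k)
        self.classes_ = classes
        self.feature_names_ = tuple(feature_names) if feature_names is not None else None
        m = self.config.bootstrap_size if self.config.bootstrap_size is not None else n
        max_depth = -1 if self.config.max_depth is None else self.config.max_depth
        mf = self.config.resolved_max_features(k)
        y_enc = np.ascontiguousarray(y_enc, dtype=np.int64)
        seeds = np.random.SeedSequence(self.config.seed).generate_state(
            self.config.n_trees, dtype=np.uint32
        )
        self.trees_ = []
        importances = np.zeros((self.config.n_trees, k))
        for t in range(self.config.n_trees):
            tree = _fit_tree(
                X,
                y_enc,
                classes.size,
                m,
                mf,
                max_depth,
                self.config.min_samples_split,
                int(seeds[t]),
                self.config.bootstrap,
            )
            self.trees_.append(tree[:5])
            importances[t] = tree[5]
        self.tree_importances_ = importances
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise ValueError("forest is not fitted")
        X = np.ascontiguousarray(X, dtype=np.float64)
        votes = np.zeros((X.shape[0], self.classes_.size), dtype=np.int64)
        for feat, thr, left, right, leaf in self.trees_:
            _tree_votes(feat, thr, left, right, leaf, X, votes)
        return self.classes_[np.argmax(votes, axis=1)]

    def feature_importances(self, normalize: bool = True) -> np.ndarray:
        """MDI: per-feature impurity decrease averaged over trees."""
        if self.tree_importances_ is None:
            raise ValueError("forest is not fitted")
        raw = self.tree_importances_.mean(axis=0)
        if not normalize:
            return raw
        total = raw.sum()
        return raw / total if total > 0 else raw


def train_forest(data: LabeledTable, config: ForestConfig) -> RandomForest:
    forest = RandomForest(config)
    forest.fit(data.X, data.y, feature_names=data.feature_names)
    return forest


def mdi(forest: RandomForest, feature_names=None) -> np.ndarray:
    """Normalized mean decrease in impurity (sums to 1 when any split occurred)."""
    imp = forest.feature_importances(normalize=True)
    if feature_names is not None and len(feature_names) != imp.size:
        raise ValueError("feature_names length mismatch")
    return imp


def _fold_assignments(y: np.ndarray, folds: int, rng: np.random.Generator,
                      stratified: bool) -> np.ndarray:
    n = y.shape[0]
    fold_of = np.empty(n, dtype=np.int64)
    if stratified:
        # concatenate shuffled per-class index lists and deal modulo `folds`:
        # overall and per-class fold sizes both differ by at most 1
        pos = 0
        order = np.empty(n, dtype=np.int64)
        for cls in np.unique(y):
            cls_idx = np.flatnonzero(y == cls)
            rng.shuffle(cls_idx)
            order[pos : pos + cls_idx.size] = cls_idx
            pos += cls_idx.size
    else:
        order = rng.permutation(n)
    fold_of[order] = np.arange(n) % folds
    return fold_of


def cv_accuracy(
    data: LabeledTable,
    config: ForestConfig,
    folds: int = 10,
    seed: int | None = None,
) -> float:
    """Mean plain accuracy over a (stratified) K-fold split."""
    n = data.X.shape[0]
    if n < folds:
        raise ValueError("need at least as many samples as folds")
    classes, counts = np.unique(data.y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    stratified = bool((counts >= folds).all())
    if not stratified:
        warnings.warn(
            "a class has fewer members than folds; falling back to an "
            "unstratified split",
            stacklevel=2,
        )
    cv_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([cv_seed, 0xCF]))
    fold_of = _fold_assignments(data.y, folds, rng, stratified)
    fold_seeds = np.random.SeedSequence([cv_seed, 0xF0]).generate_state(folds)
    accs = np.empty(folds)
    for fold in range(folds):
        test = fold_of == fold
        train = ~test
        cfg = ForestConfig(
            n_trees=config.n_trees,
            max_features=config.max_features,
            bootstrap_size=config.bootstrap_size,
            bootstrap=config.bootstrap,
            max_depth=config.max_depth,
            min_samples_split=config.min_samples_split,
            seed=int(fold_seeds[fold] % (2**31)),
        )
        forest = RandomForest(cfg).fit(data.X[train], data.y[train])
        pred = forest.predict(data.X[test])
        accs[fold] = float(np.mean(pred == data.y[test]))
    return float(accs.mean())


@dataclass
class RfeIteration:
    features: tuple[str, ...]
    mdi: np.ndarray
    cv_accuracy: float


@dataclass
class ImportanceTrace:
    iterations: list[RfeIteration]
    optimal_subset: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for it_num, it in enumerate(self.iterations, start=1):
            for name, m in zip(it.features, it.mdi):
                recs.append(
                    {
                        "iteration": it_num,
                        "feature": name,
                        "mdi": float(m),
                        "cv_accuracy": it.cv_accuracy,
                    }
                )
        return pd.DataFrame(recs)


def _canonical_index(name: str) -> int:
    try:
        return CANONICAL_ORDER.index(name)
    except ValueError:
        return len(CANONICAL_ORDER)


def rfe(data: LabeledTable, config: ForestConfig, folds: int = 10) -> ImportanceTrace:
    """Recursive feature elimination by lowest MDI.

    Each iteration fits a forest on the full current table for the MDI
    ranking, records the mean CV accuracy of the current subset, then drops
    the lowest-MDI feature (ties drop the feature latest in canonical order).
    Runs down to a single feature; the optimal subset has the highest mean CV
    accuracy with ties broken towards fewer features.
    """
    current = list(data.feature_names)
    if not current:
        raise ValueError("need at least one feature")
    iterations: list[RfeIteration] = []
    X_full = data.X
    seeds = np.random.SeedSequence([config.seed, 0x5E1]).generate_state(
        2 * len(current)
    )
    for it in range(len(current), 0, -1):
        cols = [data.feature_names.index(f) for f in current]
        sub = LabeledTable(
            X=X_full[:, cols], y=data.y, feature_names=tuple(current)
        )
        cfg = ForestConfig(
            n_trees=config.n_trees,
            max_features=(
                None
                if config.max_features is None
                else min(config.max_features, len(current))
            ),
            bootstrap_size=config.bootstrap_size,
            bootstrap=config.bootstrap,
            max_depth=config.max_depth,
            min_samples_split=config.min_samples_split,
            seed=int(seeds[2 * (len(data.feature_names) - it)] % (2**31)),
        )
        forest = train_forest(sub, cfg)
        importance = forest.feature_importances(normalize=True)
        acc = cv_accuracy(
            sub, cfg, folds=folds,
            seed=int(seeds[2 * (len(data.feature_names) - it) + 1] % (2**31)),
        )
        iterations.append(
            RfeIteration(features=tuple(current), mdi=importance.copy(), cv_accuracy=acc)
        )
        if len(current) == 1:
            break
        low = importance.min()
        tied = [
            name
            for name, m in zip(current, importance)
            if m <= low + 1e-12
        ]
        drop = max(tied, key=_canonical_index)
        if len(tied) > 1:
            warnings.warn(
                f"MDI tie among {tied}; dropping {drop!r} (latest in canonical "
                "order)",
                stacklevel=2,
            )
        current.remove(drop)
    best = max(
        iterations,
        key=lambda it: (it.cv_accuracy, -len(it.features)),
    )
    return ImportanceTrace(iterations=iterations, optimal_subset=best.features)
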