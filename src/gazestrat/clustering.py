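"""Per-item K-means validation of the selected gaze features.

For every item, participants are clustered on the selected (z-scored)
features with K-means; the number of clusters is chosen by the mean
silhouette coefficient over K = 2..10,

    sc(n) = (b(n) - a(n)) / max(a(n), b(n)),

with a(n) the mean distance to same-cluster points and b(n) the mean distance
to the nearest other cluster. When two clusters emerge they are mapped to
strategies: the cluster with the higher mean proportional-time-on-matrix
(PTM) is the constructive-matching (CM) group, the other response
elimination (RE); ties fall back to RLT then LFT. Items preferring K != 2
are force-refit at K = 2 for strategy mapping, so every item contributes a
two-cluster contrast. Agreement with the mixture-model labels is summarised
as the proportion of trials labelled identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .metrics import standardize_per_item
from .mem import StrategyLabels

__all__ = [
    "ClusterResult",
    "kmeans",
    "silhouette",
    "select_k",
    "map_clusters_to_strategies",
    "consistency",
    "cluster_items",
]


def _kmeans_single(X, k, rng, max_iter, tol):
    n = X.shape[0]
    # k-means++ seeding
    centers = np.empty((k, X.shape[1]))
    first = int(rng.integers(n))
    centers[0] = X[first]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            choice = int(rng.integers(n))
        else:
            choice = int(rng.choice(n, p=d2 / total))
        centers[c] = X[choice]
        d2 = np.minimum(d2, ((X - centers[c]) ** 2).sum(axis=1))
    assign = np.full(n, -1, dtype=np.int64)
    for _ in range(max_iter):
        dist = cdist(X, centers)
        new_assign = dist.argmin(axis=1)
        for c in range(k):
            members = new_assign == c
            if members.any():
                centers_new_c = X[members].mean(axis=0)
            else:
                # reseed an empty cluster at the point farthest from its center
                far = int(np.argmax(dist[np.arange(n), new_assign]))
                centers_new_c = X[far]
                new_assign[far] = c
            shift = np.linalg.norm(centers_new_c - centers[c])
            centers[c] = centers_new_c
        if (new_assign == assign).all():
            assign = new_assign
            break
        moved = shift  # last cluster's shift; cheap convergence hint
        assign = new_assign
        if moved < tol:
            break
    wcss = float(((X - centers[assign]) ** 2).sum())
    return assign, centers, wcss


def kmeans(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
):
    """Lloyd's algorithm from k-means++ seeding, best of ``n_init`` restarts.

    Returns ``(assignments, centers, wcss)``; deterministic under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n <= k and n != k:
        raise ValueError("need n > k (or n == k for the one-point-per-cluster case)")
    if n < k:
        raise ValueError("need n >= k")
    rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
    best = None
    for _ in range(n_init):
        assign, centers, wcss = _kmeans_single(X, k, rng, max_iter, tol)
        if best is None or wcss < best[2]:
            best = (assign, centers, wcss)
    return best


def silhouette(X: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette coefficient with Euclidean distances.

    Singleton clusters score 0; a point at zero distance from everything
    (degenerate 0/0) also scores 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if labels.size < 2:
        raise ValueError("need at least 2 clusters")
    D = squareform(pdist(X))
    n = X.shape[0]
    sc = np.zeros(n)
    for i in range(n):
        same = assignments == assignments[i]
        n_same = same.sum()
        if n_same <= 1:
            sc[i] = 0.0
            continue
        a = D[i, same].sum() / (n_same - 1)
        b = min(D[i, assignments == c].mean() for c in labels if c != assignments[i])
        denom = max(a, b)
        sc[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(sc.mean())


def select_k(
    X: np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
):
    """Choose K by the highest mean silhouette over ``k_range`` (ties: smaller K)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    k_range = list(k_range)
    if X.shape[0] <= max(k_range):
        raise ValueError("need n > max(k_range)")
    by_k = {}
    for k in k_range:
        assign, _, _ = kmeans(X, k, seed=seed, n_init=n_init)
        by_k[k] = silhouette(X, assign)
    chosen = max(sorted(by_k), key=lambda k: by_k[k])  # ties -> smaller K
    return chosen, by_k


def map_clusters_to_strategies(
    assignments: np.ndarray,
    ptm: np.ndarray,
    rlt: np.ndarray | None = None,
    lft: np.ndarray | None = None,
) -> dict:
    """Map the two clusters to CM/RE by their mean PTM (ties: RLT, then LFT)."""
    assignments = np.asarray(assignments)
    clusters = np.unique(assignments)
    if clusters.size != 2:
        raise ValueError("strategy mapping requires exactly 2 clusters")
    c0, c1 = clusters

    def contrast(vals):
        if vals is None:
            return 0.0
        vals = np.asarray(vals, dtype=float)
        return float(vals[assignments == c0].mean() - vals[assignments == c1].mean())

    for vals in (ptm, rlt, lft):
        diff = contrast(vals)
        if diff > 0:
            return {int(c0): "CM", int(c1): "RE"}
        if diff < 0:
            return {int(c0): "RE", int(c1): "CM"}
    warnings.warn(
        "clusters tie on PTM, RLT and LFT; strategy mapping undefined",
        stacklevel=2,
    )
    return {int(c0): "NA", int(c1): "NA"}


def consistency(
    labels_a: StrategyLabels | np.ndarray,
    labels_b: StrategyLabels | np.ndarray,
    scope: str = "cm_re_only",
) -> float:
    """Proportion of trials labelled identically by two methods.

    ``cm_re_only`` restricts to cells where both labels are CM or RE (the
    default, since the clustering never emits IE); ``all`` uses every cell
    where both are labelled (non-NA).
    """
    a = labels_a.labels if isinstance(labels_a, StrategyLabels) else np.asarray(labels_a)
    b = labels_b.labels if isinstance(labels_b, StrategyLabels) else np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label matrices must share an index set")
    if scope == "cm_re_only":
        in_scope = np.isin(a, ("CM", "RE")) & np.isin(b, ("CM", "RE"))
    elif scope == "all":
        in_scope = (a != "NA") & (b != "NA")
    else:
        raise ValueError("scope must be 'cm_re_only' or 'all'")
    n = int(in_scope.sum())
    if n == 0:
        raise ValueError("no trials in scope")
    return float((a[in_scope] == b[in_scope]).mean())


@dataclass
class ClusterResult:
    """Per-item clustering outcome."""

    item_id: str
    chosen_k: int
    assignments: np.ndarray
    silhouette_by_k: dict
    strategy_map: dict
    centers: np.ndarray
    participant_ids: list[str] = field(default_factory=list)


def cluster_items(
    features: pd.DataFrame,
    metrics: Sequence[str] = ("ptm", "rlt", "lft"),
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
):
    """Cluster each item's participants on z-scored selected features.

    Returns ``(results, labels)``: one :class:`ClusterResult` per item, and a
    :class:`StrategyLabels` matrix from the two-cluster strategy mapping
    (items preferring K != 2 are force-refit at K = 2).
    """
    std = standardize_per_item(features, list(metrics))
    pids = list(dict.fromkeys(features["participant_id"]))
    iids = list(dict.fromkeys(features["item_id"]))
    pidx = {p: i for i, p in enumerate(pids)}
    labels = np.full((len(pids), len(iids)), "NA", dtype="<U2")
    results = []
    item_seeds = np.random.SeedSequence([seed, 0xC1]).generate_state(len(iids))
    for j, item in enumerate(iids):
        g = std[std["item_id"] == item]
        raw = features.loc[g.index]
        X = g[list(metrics)].to_numpy(dtype=float)
        iseed = int(item_seeds[j] % (2**31))
        chosen_k, by_k = select_k(X, k_range=k_range, seed=iseed, n_init=n_init)
        if chosen_k == 2:
            assign, centers, _ = kmeans(X, 2, seed=iseed, n_init=n_init)
        else:
            assign, centers, _ = kmeans(X, 2, seed=iseed, n_init=n_init)
        mapping = map_clusters_to_strategies(
            assign,
            ptm=raw["ptm"].to_numpy(dtype=float) if "ptm" in raw else None,
            rlt=raw["rlt"].to_numpy(dtype=float) if "rlt" in raw else None,
            lft=raw["lft"].to_numpy(dtype=float) if "lft" in raw else None,
        )
        row_ids = [pidx[p] for p in raw["participant_id"]]
        for r, c in zip(row_ids, assign):
            labels[r, j] = mapping[int(c)]
        results.append(
            ClusterResult(
                item_id=str(item),
                chosen_k=int(chosen_k),
                assignments=assign,
                silhouette_by_k={int(k): float(v) for k, v in by_k.items()},
                strategy_map=mapping,
                centers=centers,
                participant_ids=[str(p) for p in raw["participant_id"]],
            )
        )
    strategy_labels = StrategyLabels(
        labels=labels,
        rule="kmeans",
        rule_params={"metrics": list(metrics), "seed": seed},
        participant_ids=[str(p) for p in pids],
        item_ids=[str(it) for it in iids],
    )
    return results, strategy_labels
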