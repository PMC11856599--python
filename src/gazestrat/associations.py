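"""Descriptive statistics linking strategies to performance and difficulty.

Three analyses summarise how strategy use relates to the rest of the data:
per-item paired comparisons of the two cluster groups (paired t with the
difference-score Cohen's d = mean(diff)/sd(diff), so t = d * sqrt(N)), the
Spearman rank correlation between item difficulty (posterior-mean b_j from
the mixture-model fit) and the per-item count of response-elimination users,
and the Pearson correlation between participants' total scores and how often
they used constructive matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mem import StrategyLabels

__all__ = [
    "PairedTestResult",
    "ItemSummary",
    "paired_t_cohen",
    "difficulty_vs_re_usage",
    "score_vs_cm_usage",
    "summarize_items",
]


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    d: float
    overflow: bool = False  # zero sd of differences with a nonzero mean


def paired_t_cohen(values_a, values_b) -> PairedTestResult:
    """Paired t-test with difference-score Cohen's d.

    ``t = mean(diff) / (sd(diff)/sqrt(n))`` and ``d = mean(diff)/sd(diff)``
    with the sample (n-1) standard deviation; two-sided p from Student's t
    with n-1 degrees of freedom. A zero sd with a nonzero mean difference is
    reported as an overflow (t, d infinite).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing pairs are not allowed")
    diff = a - b
    mean = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return PairedTestResult(t=0.0, p=1.0, d=0.0)
        sign = float(np.sign(mean))
        return PairedTestResult(
            t=sign * np.inf, p=0.0, d=sign * np.inf, overflow=True
        )
    t = mean / (sd / np.sqrt(n))
    d = mean / sd
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(t=float(t), p=float(p), d=float(d))


def difficulty_vs_re_usage(difficulty, re_counts):
    """Spearman rho (average ranks for ties, t-approximation p) between
    item difficulty and the per-item number of response-elimination users."""
    x = np.asarray(difficulty, dtype=float)
    y = np.asarray(re_counts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 items of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def score_vs_cm_usage(trials: pd.DataFrame, labels: StrategyLabels):
    """Pearson r between per-participant total score and CM-usage count.

    ``trials`` needs participant_id and ra columns (one row per trial).
    """
    if not {"participant_id", "ra"}.issubset(trials.columns):
        raise ValueError("trials table needs participant_id and ra columns")
    scores = trials.groupby("participant_id", sort=False)["ra"].sum()
    lab = labels.to_frame()
    cm_counts = (
        lab.assign(is_cm=lab["label"] == "CM")
        .groupby("participant_id", sort=False)["is_cm"]
        .sum()
    )
    common = scores.index.intersection(cm_counts.index)
    if len(common) < 3:
        raise ValueError("need >= 3 participants")
    x = scores.loc[common].to_numpy(dtype=float)
    y = cm_counts.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ItemSummary:
    """Per-item cluster contrasts and difficulty."""

    item_id: str
    cluster_means: dict  # strategy -> {metric -> mean}
    n_per_cluster: dict  # strategy -> count
    re_count: int
    difficulty: float

    def as_record(self) -> dict:
        rec = {"item_id": self.item_id, "re_count": self.re_count,
               "difficulty": self.difficulty}
        for strat, means in self.cluster_means.items():
            rec[f"n_{strat.lower()}"] = self.n_per_cluster.get(strat, 0)
            for metric, m in means.items():
                rec[f"{metric}_{strat.lower()}"] = m
        return rec


def summarize_items(
    features: pd.DataFrame,
    cluster_labels: StrategyLabels,
    difficulty: np.ndarray,
    metrics=("ptm", "rlt", "lft", "ra", "rt"),
) -> list[ItemSummary]:
    """Per-item group means of the metrics by mapped cluster strategy."""
    lab = cluster_labels.to_frame()
    merged = features.merge(
        lab[["participant_id", "item_id", "label"]],
        on=["participant_id", "item_id"],
    )
    item_ids = cluster_labels.item_ids
    if len(difficulty) != len(item_ids):
        raise ValueError("difficulty vector length mismatch")
    out = []
    for j, item in enumerate(item_ids):
        g = merged[merged["item_id"] == item]
        means = {}
        ns = {}
        for strat in ("CM", "RE"):
            sub = g[g["label"] == strat]
            ns[strat] = int(len(sub))
            means[strat] = {
                m: (float(sub[m].mean()) if len(sub) else float("nan"))
                for m in metrics
                if m in g.columns
            }
        out.append(
            ItemSummary(
                item_id=str(item),
                cluster_means=means,
                n_per_cluster=ns,
                re_count=ns["RE"],
                difficulty=float(difficulty[j]),
            )
        )
    return out
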