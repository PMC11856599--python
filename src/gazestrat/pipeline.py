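"""End-to-end orchestration: simulate -> metrics -> MEM -> labels -> RFE ->
clustering -> associations, with a manifest for reproducibility.

Every stage communicates only through files in the run directory, so deleting
an intermediate and re-running downstream stages from files reproduces the
same results. One global seed deterministically derives all stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations, clustering, forest, mem, metrics, simulate

__all__ = ["RunConfig", "run_all", "STAGES"]

STAGES = (
    "simulate",
    "metrics",
    "fit-mem",
    "identify",
    "select-features",
    "cluster",
    "analyze",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML round-trippable)."""

    seed: int
    outdir: str = "runs/default"
    # simulation (ignored when fixations/trials point at existing logs)
    simulate_input: bool = True
    fixations_path: str | None = None
    trials_path: str | None = None
    n_participants: int = 192
    n_items: int = 36
    include_hybrid: bool = False
    hybrid_proportion: float = 0.1
    # mixture model
    mem_metrics: tuple[str, ...] = mem.DEFAULT_METRICS
    chains: int = 4
    iterations: int = 5000
    identify_rule: str = "hpd"  # "hpd" | "cutoff"
    hpd_level: float = 0.95
    cutoff: float = 0.5
    posterior_thin: int = 10
    # feature selection
    classes: int = 2
    n_trees: int = 500
    cv_folds: int = 10
    # clustering
    cluster_metrics: tuple[str, ...] | None = None  # default: selected subset
    k_min: int = 2
    k_max: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for name in ("mem_metrics", "cluster_metrics"):
            val = getattr(cfg, name)
            if isinstance(val, list):
                setattr(cfg, name, tuple(val))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for name in ("mem_metrics", "cluster_metrics"):
            if isinstance(d[name], tuple):
                d[name] = list(d[name])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.stages = []
        self.config = config
        self.warnings: list[str] = []

    def record(self, stage, inputs, outputs, seed, wall_time):
        self.stages.append(
            {
                "stage": stage,
                "inputs": {str(p.name): _sha256(p) for p in inputs},
                "outputs": {str(p.name): _sha256(p) for p in outputs},
                "seed": seed,
                "wall_time_s": wall_time,
            }
        )

    def write(self, path: Path) -> None:
        payload = {
            "config": asdict(self.config),
            "stages": self.stages,
            "warnings": self.warnings,
        }
        path.write_text(json.dumps(payload, indent=1, default=str))


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order; returns the manifest dictionary.

    Any stage failure raises with the stage name attached; outputs of earlier
    stages are retained in the run directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    state: dict = {}
    for stage in STAGES:
        start = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                inputs, outputs = _run_stage(stage, config, outdir, state)
            for w in caught:
                manifest.warnings.append(f"{stage}: {w.message}")
        except Exception as exc:
            manifest.write(outdir / "manifest.json")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(
            stage, inputs, outputs, config.stage_seed(stage),
            round(time.perf_counter() - start, 3),
        )
    manifest.write(outdir / "manifest.json")
    return json.loads((outdir / "manifest.json").read_text())


def _run_stage(stage, config, outdir, state):
    if stage == "simulate":
        if not config.simulate_input:
            for name, p in (
                ("fixations", config.fixations_path),
                ("trials", config.trials_path),
            ):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"{name} path {p!r} missing and simulation not requested"
                    )
            return [], []
        sim_cfg = simulate.SimConfig(
            seed=config.stage_seed("simulate"),
            n_participants=config.n_participants,
            n_items=config.n_items,
            include_hybrid=config.include_hybrid,
            hybrid_proportion=config.hybrid_proportion,
        )
        simulate.write_dataset(sim_cfg, outdir)
        return [], [outdir / f for f in ("fixations.csv", "trials.csv", "truth.json")]

    if stage == "metrics":
        fix_path = Path(config.fixations_path or outdir / "fixations.csv")
        tri_path = Path(config.trials_path or outdir / "trials.csv")
        fixations = pd.read_csv(fix_path)
        trials = pd.read_csv(tri_path)
        features = metrics.compute_features_table(fixations, trials)
        features.to_csv(outdir / "features.csv", index=False)
        return [fix_path, tri_path], [outdir / "features.csv"]

    if stage == "fit-mem":
        features = pd.read_csv(outdir / "features.csv")
        data = mem.MemData.from_features(features, metrics=config.mem_metrics)
        post = mem.fit(
            data,
            mem.SamplerConfig(
                chains=config.chains,
                iterations=config.iterations,
                seed=config.stage_seed("fit-mem"),
            ),
        )
        state["posterior"] = post
        post.to_frame(thin=config.posterior_thin).to_csv(
            outdir / "posterior.csv", index=False
        )
        (outdir / "diagnostics.json").write_text(
            json.dumps(post.diagnostics, indent=1)
        )
        return [outdir / "features.csv"], [
            outdir / "posterior.csv",
            outdir / "diagnostics.json",
        ]

    if stage == "identify":
        post = state["posterior"]
        if config.identify_rule == "hpd":
            labels = mem.identify_hpd(post, level=config.hpd_level)
        elif config.identify_rule == "cutoff":
            labels = mem.identify_cutoff(post, cutoff=config.cutoff)
        else:
            raise ValueError(f"unknown identify rule {config.identify_rule!r}")
        state["mem_labels"] = labels
        labels.to_frame().to_csv(outdir / "labels.csv", index=False)
        return [outdir / "posterior.csv"], [outdir / "labels.csv"]

    if stage == "select-features":
        features = pd.read_csv(outdir / "features.csv")
        labels_df = pd.read_csv(outdir / "labels.csv")
        table = forest.LabeledTable.from_features_and_labels(
            features, labels_df, classes=config.classes
        )
        trace = forest.rfe(
            table,
            forest.ForestConfig(
                n_trees=config.n_trees, seed=config.stage_seed("select-features")
            ),
            folds=config.cv_folds,
        )
        state["trace"] = trace
        trace.to_frame().to_csv(outdir / "importance_trace.csv", index=False)
        (outdir / "selected_features.json").write_text(
            json.dumps({"selected": list(trace.optimal_subset)}, indent=1)
        )
        return [outdir / "features.csv", outdir / "labels.csv"], [
            outdir / "importance_trace.csv",
            outdir / "selected_features.json",
        ]

    if stage == "cluster":
        features = pd.read_csv(outdir / "features.csv")
        selected = json.loads((outdir / "selected_features.json").read_text())[
            "selected"
        ]
        cluster_metrics = config.cluster_metrics or tuple(selected)
        results, clabels = clustering.cluster_items(
            features,
            metrics=cluster_metrics,
            k_range=range(config.k_min, config.k_max + 1),
            seed=config.stage_seed("cluster"),
        )
        state["cluster_labels"] = clabels
        state["cluster_results"] = results
        clabels.to_frame().rename(columns={"label": "strategy"}).assign(
            cluster=lambda d: (d["strategy"] == "CM").astype(int)
        ).to_csv(outdir / "clusters.csv", index=False)
        pd.DataFrame(
            [
                {"item_id": r.item_id, "k": k, "mean_sc": v}
                for r in results
                for k, v in sorted(r.silhouette_by_k.items())
            ]
        ).to_csv(outdir / "silhouette.csv", index=False)
        cons = clustering.consistency(clabels, state["mem_labels"], scope="cm_re_only")
        (outdir / "consistency.json").write_text(
            json.dumps({"clustering_vs_mem": cons, "scope": "cm_re_only"}, indent=1)
        )
        return [outdir / "features.csv", outdir / "selected_features.json"], [
            outdir / "clusters.csv",
            outdir / "silhouette.csv",
            outdir / "consistency.json",
        ]

    if stage == "analyze":
        features = pd.read_csv(outdir / "features.csv")
        post = state["posterior"]
        clabels = state["cluster_labels"]
        mem_labels = state["mem_labels"]
        difficulty = post.b_mean
        summaries = associations.summarize_items(features, clabels, difficulty)
        pd.DataFrame([s.as_record() for s in summaries]).to_csv(
            outdir / "item_summaries.csv", index=False
        )
        out = {}
        for metric in ("ptm", "rlt", "lft", "ra", "rt"):
            cm_vals = [s.cluster_means["CM"].get(metric, np.nan) for s in summaries]
            re_vals = [s.cluster_means["RE"].get(metric, np.nan) for s in summaries]
            ok = [
                (a, b)
                for a, b in zip(cm_vals, re_vals)
                if not (np.isnan(a) or np.isnan(b))
            ]
            if len(ok) >= 2:
                res = associations.paired_t_cohen(
                    [a for a, _ in ok], [b for _, b in ok]
                )
                out[f"paired_{metric}"] = {
                    "t": res.t, "p": res.p, "d": res.d, "overflow": res.overflow,
                }
        re_counts = [s.re_count for s in summaries]
        rho, p_rho = associations.difficulty_vs_re_usage(difficulty, re_counts)
        out["spearman_difficulty_re"] = {"rho": rho, "p": p_rho}
        r, p_r = associations.score_vs_cm_usage(features, mem_labels)
        out["pearson_score_cm"] = {"r": r, "p": p_r}
        (outdir / "associations.json").write_text(
            json.dumps(out, indent=1, default=float)
        )
        return [outdir / "features.csv", outdir / "clusters.csv"], [
            outdir / "item_summaries.csv",
            outdir / "associations.json",
        ]

    raise ValueError(f"unknown stage {stage!r}")
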