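"""End-to-end workflow orchestration.

Runs the full landscape analysis in a fixed stage order — gene
activity, rule partitions, per-sample MILP landscapes, the entropy
prerequisite, PCA + loadings selection, redundancy flags, aggregation
adjustment, hierarchical clustering, differentiating reactions — and
writes every intermediate plus a JSON manifest (parameters, seed,
package versions, per-stage output checksums) to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .activity import ActivityTable, binarize, partition_reactions, read_counts_tsv, scale_counts
from .adjustment import aggregate, detect_redundant_groups
from .entropy import random_baseline, reaction_graph, rule_group_entropies
from .landscape import MilpConfig, compute_landscapes
from .network import MetabolicNetwork, read_json, read_sbml
from .stats import cluster_landscapes, differentiating_reactions, pca, select_variables

__all__ = ["WorkflowConfig", "run_workflow", "STAGES"]

log = logging.getLogger(__name__)

STAGES = (
    "activity",
    "partition",
    "landscapes",
    "entropy",
    "pca_selection",
    "flags",
    "adjustment",
    "clustering",
    "differentiating",
)


@dataclass
class WorkflowConfig:
    model_path: str | None = None
    counts_path: str | None = None
    out_dir: str = "metaland_out"
    activity_threshold: float = 5.0
    scale: bool = True
    epsilon: float = 1.0
    pca_k: int = 3
    f_spec: str = "frac:0.5"
    select_k: int = 2
    jaccard_fraction: float = 0.25
    percentile_cut: float = 5.0
    baseline_samples: int = 1000
    cluster_k: int = 2
    aggregate_all: bool = False
    seed: int = 0
    make_plots: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "WorkflowConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_network(cfg: WorkflowConfig, network: MetabolicNetwork | None) -> MetabolicNetwork:
    if network is not None:
        return network
    if cfg.model_path is None:
        raise ValueError("workflow needs a model_path or an in-memory network")
    path = Path(cfg.model_path)
    if path.suffix.lower() == ".json":
        return read_json(path)
    return read_sbml(path)


def run_workflow(
    config: WorkflowConfig,
    network: MetabolicNetwork | None = None,
    activities: ActivityTable | None = None,
) -> dict:
    """Execute all stages and return the run manifest.

    ``network`` / ``activities`` may be passed in memory (e.g. from the
    synthetic generators) instead of ``model_path`` / ``counts_path``.
    Any stage failure aborts with the stage name; the outputs of
    completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = _load_network(config, network)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "network_summary": net.summary(),
        "stages": [],
    }

    def record(stage: str, outputs: dict[str, Path], **info) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {k: str(p) for k, p in outputs.items()},
                "checksums": {k: _sha256(p) for k, p in outputs.items()},
                **info,
            }
        )
        log.info("stage %-14s done: %s", stage, {k: str(v) for k, v in outputs.items()})

    stage = "activity"
    try:
        if activities is None:
            if config.counts_path is None:
                raise ValueError("workflow needs counts_path or in-memory activities")
            counts = read_counts_tsv(config.counts_path)
            if config.scale:
                counts = scale_counts(counts)
            activities = binarize(counts, threshold=config.activity_threshold)
        act_path = out / "activity.tsv"
        activities.frame.to_csv(act_path, sep="\t")
        record(stage, {"activity": act_path}, threshold=activities.threshold,
               n_genes=len(activities.genes), n_samples=len(activities.samples))

        stage = "partition"
        part_rows = []
        for s in activities.samples:
            p = partition_reactions(net, activities.sample_activity(s), sample=s)
            part_rows.append({"sample": s, "n_A": len(p.A), "n_I": len(p.I),
                              "n_unconstrained": len(p.unconstrained)})
        part_path = out / "partitions.tsv"
        pd.DataFrame(part_rows).to_csv(part_path, sep="\t", index=False)
        record(stage, {"partitions": part_path})

        stage = "landscapes"
        milp_cfg = MilpConfig(epsilon=config.epsilon)
        lands = compute_landscapes(net, activities, config=milp_cfg)
        land_path = out / "landscapes.tsv"
        lands.to_csv(land_path, sep="\t")
        record(stage, {"landscapes": land_path}, epsilon=config.epsilon)

        stage = "entropy"
        graph = reaction_graph(net)
        from .network import rule_groups as _rg

        sizes = sorted({g.size for g in _rg(net)})
        baseline = random_baseline(graph, sizes, n_samples=config.baseline_samples,
                                   seed=config.seed) if sizes else {}
        ents = rule_group_entropies(net, graph, baseline=baseline)
        ent_path = out / "entropy.tsv"
        ents.to_csv(ent_path, sep="\t", index=False)
        outputs = {"entropy": ent_path}
        if config.make_plots and baseline:
            from .plots import plot_entropy_envelope

            plot_path = out / "entropy_envelope.png"
            plot_entropy_envelope(ents, baseline, plot_path)
            outputs["plot"] = plot_path
        record(stage, outputs, baseline_samples=config.baseline_samples)

        stage = "pca_selection"
        k = min(config.pca_k, len(lands) - 1, lands.shape[1])
        dec = pca(lands, k=k)
        selection = select_variables(dec, f=config.f_spec, k=min(config.select_k, k))
        scores_path = out / "pca_scores.tsv"
        loadings_path = out / "pca_loadings.tsv"
        sel_path = out / "selected_reactions.tsv"
        dec.scores.to_csv(scores_path, sep="\t")
        dec.loadings.to_csv(loadings_path, sep="\t")
        pd.Series(selection.selected_ids, name="reaction").to_csv(sel_path, sep="\t", index=False)
        outputs = {"scores": scores_path, "loadings": loadings_path, "selected": sel_path}
        if config.make_plots:
            from .plots import plot_scores

            plot_path = out / "pca_scores.png"
            plot_scores(dec, plot_path)
            outputs["plot"] = plot_path
        record(stage, outputs, k=k, f=config.f_spec, n_selected=len(selection.selected))

        stage = "flags"
        flagged = detect_redundant_groups(selection, ents, net,
                                          percentile_cut=config.percentile_cut)
        flag_path = out / "flags.tsv"
        pd.DataFrame(
            [{"rule": g.rule.render(), "size": g.size, "reactions": ";".join(g.reactions)}
             for g in flagged]
        ).to_csv(flag_path, sep="\t", index=False)
        record(stage, {"flags": flag_path}, n_flagged=len(flagged))

        stage = "adjustment"
        rules = None if config.aggregate_all else {g.rule for g in flagged}
        adjusted = aggregate(lands, net, rules=rules)
        adj_path = out / "adjusted.tsv"
        adjusted.frame.to_csv(adj_path, sep="\t")
        record(stage, {"adjusted": adj_path},
               n_columns_before=lands.shape[1], n_columns_after=adjusted.frame.shape[1])

        stage = "clustering"
        labels, _ = cluster_landscapes(adjusted.frame, k=config.cluster_k)
        lab_path = out / "clusters.tsv"
        labels.to_csv(lab_path, sep="\t")
        record(stage, {"clusters": lab_path}, k=config.cluster_k)

        stage = "differentiating"
        groups = sorted(labels.unique())
        a = adjusted.frame.loc[labels == groups[0]]
        b = adjusted.frame.loc[labels == groups[-1]]
        binarised = (adjusted.frame >= 0.5).astype(int)
        called = differentiating_reactions(
            binarised.loc[a.index], binarised.loc[b.index],
            fraction=config.jaccard_fraction,
        ) if len(groups) > 1 and len(a) and len(b) else ()
        diff_path = out / "differentiating.tsv"
        pd.Series(called, name="reaction").to_csv(diff_path, sep="\t", index=False)
        record(stage, {"differentiating": diff_path}, n_called=len(called))
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"workflow stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
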