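"""End-to-end orchestration of the five pipeline stages.

Stages: (1) QC + normalization, (2) batch-aware embedding, Leiden
clustering and NK gating with re-clustering, (3) diffusion pseudotime
and lineage occupancy, (4) spline dynamic-gene scoring and the
random-forest stability panel, (5) prior-constrained GRN inference
with centralities, modules and optional enrichment.  Every stage
writes its outputs into the run directory as it completes, and a
manifest records parameters, seeds and SHA-256 hashes of all outputs;
with the deterministic linear embedding backend, two runs with the
same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamic_genes import normalize_scores, pool_dynamic_sets, score_genes
from .embed_cluster import (
    batch_mixing_score,
    build_knn_graph,
    differential_expression,
    embed_batch_aware,
    identify_nk_clusters,
    leiden_cluster,
    rank_marker_genes,
)
from .enrichment import ora_hypergeometric, read_gmt
from .grn import (
    MessagePassingParams,
    annotate_outcome_bias,
    assemble_prior,
    compute_centralities,
    compute_coexpression,
    export_graph,
    filter_edges,
    mcl_modules,
    message_passing,
)
from .io_qc import QCParams, normalize_log, qc_filter, read_10x
from .panel_selection import run_panel_selection
from .trajectory import (
    assign_lineages,
    branch_occupancy,
    compare_occupancy,
    compute_diffusion_map,
    compute_dpt,
    lineage_pseudotime,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative configuration; every stage parameter is surfaced."""

    data_dir: str = ""
    out_dir: str = "run"
    tf_target_files: list[str] = field(default_factory=list)
    ppi_file: str | None = None
    gmt_file: str | None = None
    tf_list_file: str | None = None
    # QC
    min_genes: int = 200
    max_mito: float = 0.10
    target_sum: float = 1e4
    # embedding / clustering
    dim: int = 20
    backend: str = "linear"
    batch_key: str = "batch"
    knn_k: int = 15
    resolution_full: float = 1.0
    resolution_nk: float = 0.3
    nk_markers: list[str] = field(default_factory=lambda: ["NCAM1", "FCGR3A"])
    nk_quantile: float = 0.25
    root_markers: list[str] = field(default_factory=lambda: ["SELL", "XCL1"])
    # trajectory
    root_cluster: int | str = "auto"
    lineage_map: dict | str = "auto"
    n_comps: int = 15
    bins: int = 10
    smoothing_window: int = 3
    # dynamics
    n_splines: int = 10
    # panel
    k_top: int = 15
    trees: int = 500
    panel_threshold: float = 0.5
    relapse_outcomes: list[str] = field(default_factory=lambda: ["early_relapse", "late_relapse"])
    control_outcomes: list[str] = field(default_factory=lambda: ["TFR", "control"])
    # GRN
    alpha: float = 0.05
    lambda_l2: float = 0.1
    iters: int = 150
    edge_filter_mode: str = "top_fraction"
    edge_filter_value: float = 0.015
    inflation: float = 2.2
    pagerank_percentile: float = 90.0
    min_string_score: float = 700.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


class _StageError(RuntimeError):
    pass


class _Done(Exception):
    """Internal: raised to stop after the stage named by ``until``."""


def run_pipeline(cfg: PipelineConfig, until: str | None = None) -> Path:
    """Execute stages in order (optionally stopping after ``until``).

    Any stage failure aborts with the stage name and cause.  Outputs
    per stage: QC summary, cluster labels + marker table, pseudotime +
    occupancy + rank tests, dynamic-gene scores + pooled set, panel
    table + fold metrics, GRN edge list + centralities + modules +
    exports, optional enrichment, and a manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}
    stage = "setup"
    try:
        # ------------------------------------------------ stage 1: QC
        stage = "qc"
        qc_params = QCParams(
            min_genes_per_cell=cfg.min_genes,
            max_mito_fraction=cfg.max_mito,
            target_sum=cfg.target_sum,
        )
        m = read_10x(cfg.data_dir)
        n_before = m.n_cells
        m = qc_filter(m, qc_params)
        norm = normalize_log(m, qc_params)
        (out / "qc_summary.json").write_text(
            json.dumps(
                {"cells_before": n_before, "cells_after": m.n_cells, "genes": m.n_genes},
                indent=2,
            )
        )
        outputs[stage] = ["qc_summary.json"]
        if until == stage:
            raise _Done

        # --------------------------------- stage 2: embed + cluster + gate
        stage = "embed_cluster"
        batches = norm.cell_meta[cfg.batch_key].to_numpy()
        emb_full = embed_batch_aware(norm, batches, d=cfg.dim, backend=cfg.backend, seed=cfg.seed)
        graph_full = build_knn_graph(emb_full, k=cfg.knn_k)
        labels_full = leiden_cluster(graph_full, resolution=cfg.resolution_full, seed=cfg.seed)
        mixing = batch_mixing_score(emb_full, batches, k=cfg.knn_k)
        nk_clusters = identify_nk_clusters(
            norm, labels_full, markers=tuple(cfg.nk_markers), quantile=cfg.nk_quantile
        )
        nk_mask = np.isin(labels_full.labels, sorted(nk_clusters))
        if not nk_mask.any():
            raise ValueError("NK gate selected no cells")
        nk = norm.subset_cells(nk_mask)
        emb_nk = embed_batch_aware(
            nk, nk.cell_meta[cfg.batch_key].to_numpy(), d=min(cfg.dim, nk.n_genes - 1),
            backend=cfg.backend, seed=cfg.seed,
        )
        graph_nk = build_knn_graph(emb_nk, k=cfg.knn_k)
        labels_nk = leiden_cluster(graph_nk, resolution=cfg.resolution_nk, seed=cfg.seed)
        markers_tab = rank_marker_genes(nk, labels_nk)
        _write_tsv(markers_tab, out / "markers.tsv")
        cell_tab = nk.cell_meta.reset_index()
        cell_tab["cluster"] = labels_nk.labels
        _write_tsv(cell_tab, out / "nk_cells.tsv")
        (out / "embedding_summary.json").write_text(
            json.dumps(
                {
                    "batch_mixing_score": mixing,
                    "n_full_clusters": labels_full.n_clusters,
                    "nk_clusters_flagged": sorted(int(c) for c in nk_clusters),
                    "n_nk_cells": int(nk.n_cells),
                    "n_nk_clusters": labels_nk.n_clusters,
                },
                indent=2,
            )
        )
        outputs[stage] = ["markers.tsv", "nk_cells.tsv", "embedding_summary.json"]
        if until == stage:
            raise _Done

        # ------------------------------------------ stage 3: trajectory
        stage = "trajectory"
        dm = compute_diffusion_map(graph_nk, n_comps=min(cfg.n_comps, nk.n_cells - 2))
        if cfg.root_cluster == "auto":
            root_cluster = _root_cluster_by_markers(nk, labels_nk, cfg.root_markers)
        else:
            root_cluster = int(cfg.root_cluster)
        root_cells = np.flatnonzero(labels_nk.labels == root_cluster)
        dpt, root_cell = compute_dpt(dm, root_cells)
        if cfg.lineage_map == "auto":
            lineage_map = _auto_lineage_map(labels_nk, dpt, root_cluster)
        else:
            lineage_map = {k: list(v) for k, v in cfg.lineage_map.items()}
        membership = assign_lineages(labels_nk, lineage_map)
        pt = lineage_pseudotime(dpt, membership, root_cluster, root_cell)
        outcomes = nk.cell_meta["outcome"].to_numpy()
        stats, occ_frames = {}, []
        for lin in sorted(membership):
            occ = branch_occupancy(
                pt.pseudotime[lin], outcomes, n_bins=cfg.bins,
                smoothing_window=cfg.smoothing_window, lineage=lin,
            )
            occ_frames.append(occ.fractions.assign(lineage=lin).reset_index(names="group"))
            stats[lin] = compare_occupancy(pt.pseudotime[lin], outcomes)
        _write_tsv(pd.concat(occ_frames, ignore_index=True), out / "occupancy.tsv")
        (out / "trajectory_stats.json").write_text(json.dumps(
            {"root_cluster": int(root_cluster), "lineage_map": lineage_map, "tests": stats},
            indent=2,
        ))
        traj_tab = pd.DataFrame({"cell_id": nk.cell_ids})
        for lin in sorted(membership):
            traj_tab[f"pseudotime_{lin}"] = pt.pseudotime[lin]
            traj_tab[f"member_{lin}"] = membership[lin]
        _write_tsv(traj_tab, out / "pseudotime.tsv")
        outputs[stage] = ["occupancy.tsv", "trajectory_stats.json", "pseudotime.tsv"]
        if until == stage:
            raise _Done

        # ---------------------------------------- stage 4: dynamics + panel
        stage = "dynamics"
        dense_nk = nk.dense()
        tf_list = _load_tf_list(cfg)
        score_tables = {}
        for lin in sorted(membership):
            mask = membership[lin]
            raw = score_genes(dense_nk[mask], pt.pseudotime[lin][mask], n_splines=cfg.n_splines)
            score_tables[lin] = normalize_scores(
                pd.Series(raw, index=nk.gene_ids), lineage=lin
            )
        lins = sorted(score_tables)
        pooled = pool_dynamic_sets(score_tables[lins[0]], score_tables[lins[1]], tf_list)
        _write_tsv(pd.concat(score_tables.values(), ignore_index=True), out / "gam_scores.tsv")
        (out / "pooled_genes.txt").write_text("\n".join(sorted(pooled.pooled)) + "\n")
        outputs[stage] = ["gam_scores.tsv", "pooled_genes.txt"]
        if until == stage:
            raise _Done

        stage = "panel"
        lineage_clusters = tuple(sorted({c for cl in lineage_map.values() for c in cl}))
        panel, fold_results = run_panel_selection(
            nk, pooled.pooled, labels_nk, clusters=lineage_clusters,
            relapse_outcomes=tuple(cfg.relapse_outcomes),
            control_outcomes=tuple(cfg.control_outcomes),
            k=cfg.k_top, n_trees=cfg.trees, threshold=cfg.panel_threshold, seed=cfg.seed,
        )
        panel_tab = panel.table.rename(
            columns={
                "gene": "Gene",
                "count_in_topk": f"Count in Top{cfg.k_top}",
                "n_validations": "Number of Validations",
                "frequency": "Frequency",
            }
        )
        _write_tsv(panel_tab, out / "panel.tsv")
        (out / "fold_metrics.json").write_text(json.dumps(
            [
                {"fold_id": fr.fold_id, "accuracy": fr.accuracy, "roc_auc": fr.roc_auc,
                 "top_k_genes": fr.top_k_genes}
                for fr in fold_results
            ],
            indent=2,
        ))
        outputs[stage] = ["panel.tsv", "fold_metrics.json"]
        if until == stage:
            raise _Done

        # ------------------------------------------------- stage 5: GRN
        stage = "grn"
        if not cfg.tf_target_files or cfg.ppi_file is None:
            raise FileNotFoundError(
                "GRN stage requires tf_target_files and ppi_file in the config"
            )
        for p in list(cfg.tf_target_files) + [cfg.ppi_file]:
            if not Path(p).exists():
                raise FileNotFoundError(f"prior file not found: {p}")
        prior = assemble_prior(
            cfg.tf_target_files, cfg.ppi_file, norm.gene_ids,
            min_string_score=cfg.min_string_score,
        )
        C = compute_coexpression(dense_nk)
        grn = message_passing(
            prior, C,
            MessagePassingParams(alpha=cfg.alpha, lambda_l2=cfg.lambda_l2, n_iter=cfg.iters),
        )
        edges = filter_edges(grn, mode=cfg.edge_filter_mode, value=cfg.edge_filter_value)
        cents = compute_centralities(edges, tf_ids=grn.tf_ids)
        modules = mcl_modules(edges, inflation=cfg.inflation)
        relapse_mask = nk.cell_meta["outcome"].isin(cfg.relapse_outcomes).to_numpy()
        control_mask = nk.cell_meta["outcome"].isin(cfg.control_outcomes).to_numpy()
        de = differential_expression(dense_nk[relapse_mask | control_mask],
                                     control_mask[relapse_mask | control_mask])
        de.index = nk.gene_ids
        ann, per_tf = annotate_outcome_bias(edges, de)
        _write_tsv(edges, out / "grn_edges.tsv")
        _write_tsv(cents, out / "grn_centralities.tsv")
        _write_tsv(
            pd.DataFrame(sorted(modules.items()), columns=["node", "module"]),
            out / "grn_modules.tsv",
        )
        _write_tsv(ann, out / "grn_outcome_annotation.tsv")
        export_graph(edges, out / "grn.sif", fmt="SIF")
        export_graph(edges, out / "grn.graphml", fmt="GraphML",
                     centralities=cents, annotations=ann)
        outputs[stage] = [
            "grn_edges.tsv", "grn_centralities.tsv", "grn_modules.tsv",
            "grn_outcome_annotation.tsv", "grn.sif", "grn.graphml",
        ]
        if until == stage:
            raise _Done

        # ------------------------------------------ stage 6: enrichment
        if cfg.gmt_file:
            stage = "enrichment"
            col = read_gmt(cfg.gmt_file, universe=set(norm.gene_ids))
            res = ora_hypergeometric(set(panel.selected_panel), col)
            _write_tsv(res, out / "enrichment_panel.tsv")
            outputs[stage] = ["enrichment_panel.tsv"]
    except _Done:
        pass
    except Exception as exc:
        raise _StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": asdict(cfg),
        "stages": {
            st: {name: _sha256(out / name) for name in names}
            for st, names in outputs.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _root_cluster_by_markers(nk, labels, root_markers) -> int:
    """Pick the cluster with the highest mean z-scored root-marker expression."""
    cols = nk.gene_index([g for g in root_markers if g in set(nk.gene_ids)])
    if cols.size == 0:
        raise ValueError(f"none of the root markers {root_markers} present")
    vals = np.asarray(nk.values[:, cols].todense())
    z = (vals - vals.mean(axis=0)) / np.where(vals.std(axis=0) == 0, 1, vals.std(axis=0))
    score = z.mean(axis=1)
    best, best_score = None, -np.inf
    for c in labels.cluster_ids():
        s = score[labels.labels == c].mean()
        if s > best_score:
            best, best_score = c, s
    return int(best)


def _auto_lineage_map(labels, dpt: np.ndarray, root_cluster: int) -> dict[str, list[int]]:
    """Two lineages: shared early clusters plus one terminal each.

    Terminals are the two non-root clusters with the highest mean DPT;
    every other cluster is treated as shared between both paths.
    """
    means = {
        c: float(dpt[labels.labels == c].mean())
        for c in labels.cluster_ids()
        if c != root_cluster
    }
    if len(means) < 2:
        raise ValueError("need at least 3 clusters for two lineages")
    terminals = sorted(means, key=lambda c: -means[c])[:2]
    shared = [root_cluster] + [c for c in sorted(means) if c not in terminals]
    return {
        "L501": shared + [min(terminals)],
        "L503": shared + [max(terminals)],
    }


def _load_tf_list(cfg: PipelineConfig) -> list[str]:
    if cfg.tf_list_file and Path(cfg.tf_list_file).exists():
        return [
            line.strip()
            for line in Path(cfg.tf_list_file).read_text().splitlines()
            if line.strip()
        ]
    tfs: set[str] = set()
    for path in cfg.tf_target_files:
        if Path(path).exists():
            tfs |= set(pd.read_csv(path, sep="\t").iloc[:, 0].astype(str))
    if not tfs:
        warnings.warn("no TF list available; no TFs appended to the pooled set")
    return sorted(tfs)
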