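"""End-to-end pipeline: layers -> summary -> hybrid graph -> MCL -> modules.

The stages compose the public functions of the other modules; this module
adds configuration, artifact writing, and parameter sweeps.  Outputs are
deterministic: rerunning on identical inputs and config reproduces every
table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .coexpression import build_coexpression_layer, read_expression_tsv
from .graph_core import (MultiLayerGraph, build_summary_graph,
                         prune_by_frequency, read_edge_list, write_edge_list,
                         write_summary_tsv)
from .link_similarity import HybridParams, build_hybrid_graph, write_abc
from .mcl import MclConfig, cluster_hybrid_graph
from .metrics import (cluster_table, export_gene_sets, summarize_clusters)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "sweep",
           "load_layers", "layers_from_expression"]


@dataclass(frozen=True)
class PipelineConfig:
    """Flat bundle of every stage's tunables.

    Defaults: correlation p-value cutoff 0.01; minimum edge frequency 10;
    alpha = beta = 0.5; MCL inflation 2.0; γ grid {0.5, 0.75, 1.0} with
    minsup 5; clusters need at least 4 links and exported modules at least
    5 genes.
    """

    p_cutoff: float = 0.01
    min_edge_freq: int = 10
    alpha: float = 0.5
    beta: float = 0.5
    inflation: float = 2.0
    gammas: tuple = (0.5, 0.75, 1.0)
    minsup: int = 5
    min_cluster_links: int = 4
    min_module_genes: int = 5
    seed: int = 0

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if f.name == "gammas":
                    v = ",".join(f"{g:g}" for g in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                raw[key.strip()] = val.strip()
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "gammas":
                kwargs[f.name] = tuple(float(g) for g in v.split(","))
            elif f.type == "int" or f.name in (
                    "min_edge_freq", "minsup", "min_cluster_links",
                    "min_module_genes", "seed"):
                kwargs[f.name] = int(v)
            else:
                kwargs[f.name] = float(v)
        return cls(**kwargs)


def load_layers(paths) -> MultiLayerGraph:
    """Read per-layer edge-list TSVs into a multi-layer graph; layer ids
    are the filename stems."""
    layers = [read_edge_list(p) for p in paths]
    return MultiLayerGraph.from_layers(layers)


def layers_from_expression(paths, p_cutoff: float = 0.01,
                           positive_only: bool = False) -> MultiLayerGraph:
    """Build one coexpression layer per expression TSV."""
    layers = []
    for p in paths:
        expr = read_expression_tsv(p)
        layers.append(build_coexpression_layer(expr, p_cutoff,
                                               positive_only))
    return MultiLayerGraph.from_layers(layers)


def _hash_mlg(mlg: MultiLayerGraph) -> str:
    h = hashlib.sha256()
    for lay in mlg.layers:
        h.update(lay.layer_id.encode())
        for link in sorted(lay.edges):
            h.update(link.name().encode())
    return h.hexdigest()


def _config_comment(config: PipelineConfig) -> str:
    return " ".join(
        f"{f.name}={getattr(config, f.name)}"
        for f in dataclasses.fields(config)
    )


def run_pipeline(config: PipelineConfig, mlg: MultiLayerGraph,
                 outdir: str | Path, write_layers: bool = False) -> dict:
    """Run the full pipeline on a multi-layer graph and write the artifact
    bundle into ``outdir``.

    Returns a dict with the in-memory stage products (summary graph,
    hybrid graph, clustering, tables) alongside the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comment = _config_comment(config)

    if write_layers:
        for lay in mlg.layers:
            write_edge_list(lay, outdir / f"{lay.layer_id}.edges.tsv")

    summary_full = build_summary_graph(mlg)
    summary = prune_by_frequency(summary_full, config.min_edge_freq)
    logger.info("summary graph: %d genes, %d links (of %d before pruning)",
                len(summary.genes), summary.n_links, summary_full.n_links)
    write_summary_tsv(summary, outdir / "summary.tsv", header_comment=comment)

    params = HybridParams(alpha=config.alpha, beta=config.beta)
    hg = build_hybrid_graph(summary, params)
    logger.info("hybrid graph: %d link-nodes, %d weighted edges",
                hg.n_nodes, hg.n_edges)
    write_abc(hg, outdir / "hybrid.abc")

    clustering = cluster_hybrid_graph(hg, MclConfig(inflation=config.inflation))
    logger.info("MCL: %d clusters", clustering.n_clusters)
    with open(outdir / "clusters.txt", "w") as fh:
        for ec in clustering.clusters:
            fh.write("\t".join(l.name() for l in sorted(ec.links)) + "\n")

    table = cluster_table(clustering, summary, config.gammas, config.minsup,
                          config.min_cluster_links)
    with open(outdir / "modules.tsv", "w") as fh:
        fh.write(f"# {comment}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    summary_row = summarize_clusters(clustering, summary, mlg, config.gammas,
                                     config.minsup, config.min_cluster_links)
    with open(outdir / "summary_stats.tsv", "w") as fh:
        fh.write(f"# {comment}\n")
        summary_row.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    n_sets = export_gene_sets(clustering, outdir / "modules.gmt",
                              min_genes=config.min_module_genes)

    manifest = {
        "recolink_version": __version__,
        "config": {f.name: (list(v) if isinstance(
            (v := getattr(config, f.name)), tuple) else v)
            for f in dataclasses.fields(config)},
        "input_hash": _hash_mlg(mlg),
        "n_layers": mlg.n_layers,
        "n_genes_universe": len(mlg.genes),
        "summary_links_before_pruning": summary_full.n_links,
        "summary_links": summary.n_links,
        "summary_genes": len(summary.genes),
        "hybrid_nodes": hg.n_nodes,
        "hybrid_edges": hg.n_edges,
        "n_clusters": clustering.n_clusters,
        "n_gene_sets_exported": n_sets,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "summary": summary,
        "hybrid": hg,
        "clustering": clustering,
        "module_table": table,
        "summary_stats": summary_row,
        "manifest": manifest,
        "outdir": outdir,
    }


def sweep(config: PipelineConfig, mlg: MultiLayerGraph, outdir: str | Path,
          alphas=None, betas=None):
    """Run the pipeline over a grid of (alpha, beta), reusing the pruned
    summary graph, and collect one summary row per grid point.

    Per-point failures are recorded in the returned table (NaN metrics)
    and the sweep continues.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alphas = list(alphas) if alphas is not None else [config.alpha]
    betas = list(betas) if betas is not None else [config.beta]
    if not alphas or not betas:
        raise ValueError("sweep grid is empty")

    summary = prune_by_frequency(build_summary_graph(mlg),
                                 config.min_edge_freq)
    rows = []
    for a in alphas:
        for b in betas:
            point = {"alpha": a, "beta": b}
            try:
                hg = build_hybrid_graph(summary, HybridParams(alpha=a, beta=b))
                clustering = cluster_hybrid_graph(
                    hg, MclConfig(inflation=config.inflation))
                row = summarize_clusters(
                    clustering, summary, mlg, config.gammas, config.minsup,
                    config.min_cluster_links).iloc[0].to_dict()
                point.update({"hybrid_nodes": hg.n_nodes,
                              "hybrid_edges": hg.n_edges})
                point.update(row)
            except Exception as exc:  # keep sweeping past a bad grid point
                logger.error("sweep point alpha=%g beta=%g failed: %s",
                             a, b, exc)
                point["error"] = str(exc)
            rows.append(point)
    table = pd.DataFrame(rows)
    with open(outdir / "sweep.tsv", "w") as fh:
        fh.write(f"# {_config_comment(config)}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return table
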