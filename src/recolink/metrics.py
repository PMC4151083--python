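"""Gene modules from edge clusters, and their topological / recurrence
statistics.

An *edge cluster* is one MCL cluster of summary-graph links; the genes its
links touch form the *module*.  Because links, not genes, are partitioned,
modules from different clusters may overlap through shared genes.  Each
cluster is characterized by

* ``RE`` (edge ratio): its links as a fraction of all summary links induced
  by the module's genes,
* ``rho`` (density): its links relative to a complete graph on the module's
  genes, ``2|EC| / (|V||V-1|)``, and
* γ-approximate support: the number of layers containing at least
  ``ceil(gamma * |EC|)`` of the cluster's links.  At γ = 1 this is the
  conventional support of frequent-pattern mining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_core import Link, MultiLayerGraph, SummaryGraph

__all__ = [
    "EdgeCluster",
    "ClusterMetrics",
    "module_vertices",
    "edge_ratio",
    "cluster_density",
    "gamma_support",
    "compute_cluster_metrics",
    "cluster_table",
    "summarize_clusters",
    "export_gene_sets",
]

DEFAULT_GAMMAS = (0.5, 0.75, 1.0)


@dataclass(frozen=True)
class EdgeCluster:
    """One cluster of links (nodes of the hybrid graph)."""

    id: int
    links: frozenset

    def __post_init__(self) -> None:
        if not self.links:
            raise ValueError("an edge cluster must contain at least one link")

    def __len__(self) -> int:
        return len(self.links)


@dataclass(frozen=True)
class ClusterMetrics:
    n_links: int
    n_genes: int
    edge_ratio: float
    density: float
    gamma_supports: dict
    is_frequent: dict


def module_vertices(ec: EdgeCluster) -> frozenset:
    """The gene module induced by a cluster: the union of link endpoints."""
    return frozenset(g for link in ec.links for g in link)


def edge_ratio(ec: EdgeCluster, summary: SummaryGraph) -> float:
    """|EC| over the number of summary links induced by the module genes.

    Below 1 exactly when the summary graph holds links among the module's
    genes that the cluster itself does not contain.
    """
    genes = module_vertices(ec)
    induced = sum(
        1 for link in summary.links if link.u in genes and link.v in genes
    )
    return len(ec.links) / induced


def cluster_density(ec: EdgeCluster) -> float:
    """``2|EC| / (|V(EC)| * (|V(EC)| - 1))``: 1 iff the cluster's links form
    a complete graph on its genes."""
    nv = len(module_vertices(ec))
    return 2.0 * len(ec.links) / (nv * (nv - 1))


def _gamma_threshold(gamma: float, n_links: int) -> int:
    # round before ceil so e.g. 0.7 * 10 = 7.000000000000001 stays at 7
    return int(math.ceil(round(gamma * n_links, 9)))


def gamma_support(ec: EdgeCluster, mlg: MultiLayerGraph, gamma: float) -> int:
    """Number of layers containing at least ``ceil(gamma * |EC|)`` of the
    cluster's links."""
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    need = _gamma_threshold(gamma, len(ec.links))
    return sum(
        1 for lay in mlg.layers if len(ec.links & lay.edges) >= need
    )


def _gamma_supports_from_summary(ec: EdgeCluster, summary: SummaryGraph,
                                 gammas) -> dict:
    """Vectorized per-layer intersection counts via the occurrence matrix."""
    rows = [summary.link_index(link) for link in ec.links]
    per_layer = summary.occurrence[rows, :].sum(axis=0)
    out = {}
    for g in gammas:
        need = _gamma_threshold(g, len(ec.links))
        out[g] = int((per_layer >= need).sum())
    return out


def compute_cluster_metrics(ec: EdgeCluster, summary: SummaryGraph,
                            gammas=DEFAULT_GAMMAS,
                            minsup: int = 5) -> ClusterMetrics:
    sups = _gamma_supports_from_summary(ec, summary, gammas)
    return ClusterMetrics(
        n_links=len(ec.links),
        n_genes=len(module_vertices(ec)),
        edge_ratio=edge_ratio(ec, summary),
        density=cluster_density(ec),
        gamma_supports=sups,
        is_frequent={g: sups[g] >= minsup for g in gammas},
    )


def _size_filtered(clustering, min_cluster_links: int):
    return [ec for ec in clustering.clusters
            if len(ec.links) >= min_cluster_links]


def cluster_table(clustering, summary: SummaryGraph,
                  gammas=DEFAULT_GAMMAS, minsup: int = 5,
                  min_cluster_links: int = 4) -> pd.DataFrame:
    """Per-cluster table: one row per size-filtered cluster with its sizes,
    RE, density, γ-supports, and sorted member genes and links."""
    rows = []
    for ec in _size_filtered(clustering, min_cluster_links):
        cm = compute_cluster_metrics(ec, summary, gammas, minsup)
        genes = sorted(module_vertices(ec))
        links = sorted(ec.links)
        row = {
            "cluster_id": ec.id,
            "n_links": cm.n_links,
            "n_genes": cm.n_genes,
            "RE": cm.edge_ratio,
            "density": cm.density,
        }
        for g in gammas:
            row[f"sup_{g:g}"] = cm.gamma_supports[g]
        row["genes"] = ",".join(genes)
        row["links"] = ",".join(l.name() for l in links)
        rows.append(row)
    cols = (["cluster_id", "n_links", "n_genes", "RE", "density"]
            + [f"sup_{g:g}" for g in gammas] + ["genes", "links"])
    return pd.DataFrame(rows, columns=cols)


def summarize_clusters(clustering, summary: SummaryGraph,
                       mlg: MultiLayerGraph | None = None,
                       gammas=DEFAULT_GAMMAS, minsup: int = 5,
                       min_cluster_links: int = 4) -> pd.DataFrame:
    """One summary row over the size-filtered clusters.

    Columns: cluster count |M|, mean genes and links per cluster, mean RE
    and density, and per γ the mean support plus the count and whole-percent
    share of clusters whose γ-support reaches ``minsup``.  Percentages are
    relative to the size-filtered cluster set.  ``mlg`` is accepted for
    symmetry with :func:`gamma_support` but the occurrence matrix already
    carries the per-layer information.
    """
    kept = _size_filtered(clustering, min_cluster_links)
    row: dict = {"n_clusters": len(kept)}
    if not kept:
        for name in ("mean_genes", "mean_links", "mean_RE", "mean_density"):
            row[name] = float("nan")
        for g in gammas:
            row[f"mean_sup_{g:g}"] = float("nan")
            row[f"n_frequent_{g:g}"] = 0
            row[f"pct_frequent_{g:g}"] = 0
        return pd.DataFrame([row])
    metrics = [compute_cluster_metrics(ec, summary, gammas, minsup)
               for ec in kept]
    row["mean_genes"] = float(np.mean([m.n_genes for m in metrics]))
    row["mean_links"] = float(np.mean([m.n_links for m in metrics]))
    row["mean_RE"] = float(np.mean([m.edge_ratio for m in metrics]))
    row["mean_density"] = float(np.mean([m.density for m in metrics]))
    for g in gammas:
        sups = [m.gamma_supports[g] for m in metrics]
        nfreq = sum(1 for m in metrics if m.is_frequent[g])
        row[f"mean_sup_{g:g}"] = float(np.mean(sups))
        row[f"n_frequent_{g:g}"] = nfreq
        row[f"pct_frequent_{g:g}"] = int(round(100.0 * nfreq / len(kept)))
    return pd.DataFrame([row])


def export_gene_sets(clustering, path: str | Path,
                     min_genes: int = 5,
                     description: str = "recolink module") -> int:
    """Write modules with at least ``min_genes`` genes as GMT records
    (set name, description, tab-separated genes).  Returns the number of
    records written."""
    n = 0
    with open(path, "w") as fh:
        for ec in clustering.clusters:
            genes = sorted(module_vertices(ec))
            if len(genes) < min_genes:
                continue
            fh.write("\t".join([f"module_{ec.id}", description] + genes) + "\n")
            n += 1
    return n
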