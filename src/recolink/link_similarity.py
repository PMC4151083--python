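"""Similarities between adjacent coexpression links and the hybrid graph.

Two links of the summary graph that share a gene endpoint are compared by

* topological similarity ``S_t``: the Jaccard coefficient of the inclusive
  neighborhoods (neighbor set plus the node itself) of the two non-shared
  endpoints, and
* attribute similarity ``S_a``: the Jaccard coefficient of the sets of
  layers the two links occur in.

The hybrid similarity ``S = alpha * S_t + (1 - alpha) * S_a`` weights the
two, and pairs with ``S >= beta`` become the weighted edges of the *hybrid
graph*, whose nodes are the links themselves.  Non-adjacent link pairs are
never scored: attribute similarity alone could connect links that are far
apart in the graph, which is exactly the structure the adjacency
restriction is there to exclude.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .graph_core import Link, SummaryGraph

logger = logging.getLogger(__name__)

#: absolute tolerance for the ``S >= beta`` retention test, so pairs landing
#: exactly on beta are not lost to rounding
BETA_TOL = 1e-12

__all__ = [
    "HybridParams",
    "HybridGraph",
    "inclusive_neighbors",
    "topological_similarity",
    "attribute_similarity",
    "hybrid_similarity",
    "build_hybrid_graph",
    "write_abc",
    "read_abc",
]


@dataclass(frozen=True)
class HybridParams:
    """Weight ``alpha`` of the topological term and retention threshold
    ``beta``, both in [0, 1]."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class HybridGraph:
    """Weighted graph over links: nodes are summary-graph links, edges
    connect adjacent link pairs whose hybrid similarity passed beta."""

    nodes: tuple
    weighted_edges: tuple
    params: HybridParams

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.weighted_edges)


def inclusive_neighbors(summary: SummaryGraph, gene: str) -> frozenset:
    """Neighbors of a gene in the summary graph, plus the gene itself."""
    return summary.neighbors(gene) | {gene}


def _shared_endpoint(e1: Link, e2: Link) -> str | None:
    shared = {e1.u, e1.v} & {e2.u, e2.v}
    if len(shared) == 1:
        return next(iter(shared))
    return None  # disjoint (or identical, which callers rule out)


def topological_similarity(summary: SummaryGraph, e1: Link, e2: Link) -> float:
    """Jaccard of the inclusive neighborhoods of the non-shared endpoints.

    Returns 0 for link pairs that share no endpoint; adjacent pairs always
    score > 0 because the shared endpoint lies in both neighborhoods.
    """
    if e1 == e2:
        raise ValueError("topological similarity of a link with itself "
                         "is not defined")
    k = _shared_endpoint(e1, e2)
    if k is None:
        return 0.0
    i = e1.u if e1.v == k else e1.v
    j = e2.u if e2.v == k else e2.v
    ni = inclusive_neighbors(summary, i)
    nj = inclusive_neighbors(summary, j)
    return len(ni & nj) / len(ni | nj)


def attribute_similarity(summary: SummaryGraph, e1: Link, e2: Link) -> float:
    """Jaccard of the layer-occurrence sets of two links."""
    if e1 == e2:
        raise ValueError("attribute similarity of a link with itself "
                         "is not defined")
    r1 = summary.occurrence[summary.link_index(e1)]
    r2 = summary.occurrence[summary.link_index(e2)]
    inter = int((r1 & r2).sum())
    union = int((r1 | r2).sum())
    return inter / union


def hybrid_similarity(st: float, sa: float, alpha: float) -> float:
    """Convex combination ``alpha * st + (1 - alpha) * sa``."""
    return alpha * st + (1.0 - alpha) * sa


def build_hybrid_graph(summary: SummaryGraph, params: HybridParams,
                       keep_singletons: bool = False) -> HybridGraph:
    """Score every adjacent link pair and keep those with ``S >= beta``.

    Pairs are enumerated through per-gene incident-link lists, never the
    full quadratic link-pair grid.  In a simple graph two distinct links
    share at most one endpoint, so each adjacent pair is discovered exactly
    once.  Links left with no retained pair are dropped unless
    ``keep_singletons`` asks for them (a singleton can never join a
    multi-link cluster downstream).
    """
    incident: dict = {g: [] for g in summary.genes}
    for link in summary.links:
        incident[link.u].append(link)
        incident[link.v].append(link)

    alpha, beta = params.alpha, params.beta
    weighted = []
    used: set = set()
    for gene in summary.genes:
        links_here = incident[gene]
        for e1, e2 in itertools.combinations(links_here, 2):
            st = topological_similarity(summary, e1, e2)
            sa = attribute_similarity(summary, e1, e2)
            s = hybrid_similarity(st, sa, alpha)
            if s + BETA_TOL >= beta:
                a, b = (e1, e2) if e1 <= e2 else (e2, e1)
                weighted.append((a, b, s))
                used.add(a)
                used.add(b)
    weighted.sort(key=lambda t: (t[0], t[1]))
    if keep_singletons:
        nodes = summary.links
    else:
        nodes = tuple(l for l in summary.links if l in used)
    if not weighted:
        logger.warning("hybrid graph is empty at alpha=%.3g beta=%.3g",
                       alpha, beta)
    return HybridGraph(nodes=nodes, weighted_edges=tuple(weighted),
                       params=params)


def write_abc(hg: HybridGraph, path: str | Path) -> None:
    """Write the hybrid graph in label ABC format (``u|v  u|v  weight``),
    the native input dialect of standard MCL tooling."""
    with open(path, "w") as fh:
        for e1, e2, w in hg.weighted_edges:
            fh.write(f"{e1.name()}\t{e2.name()}\t{w:.12g}\n")


def read_abc(path: str | Path,
             params: HybridParams | None = None) -> HybridGraph:
    """Read a label ABC file back into a hybrid graph."""
    weighted = []
    nodes: set = set()
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            e1, e2 = Link.parse(parts[0]), Link.parse(parts[1])
            w = float(parts[2])
            a, b = (e1, e2) if e1 <= e2 else (e2, e1)
            weighted.append((a, b, w))
            nodes.add(a)
            nodes.add(b)
    weighted.sort(key=lambda t: (t[0], t[1]))
    return HybridGraph(nodes=tuple(sorted(nodes)),
                       weighted_edges=tuple(weighted),
                       params=params or HybridParams(alpha=0.5, beta=0.0))
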