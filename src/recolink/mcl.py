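"""Markov Clustering (MCL) of the weighted hybrid link graph.

MCL simulates flow on a graph: a column-stochastic transition matrix is
alternately *expanded* (matrix power, spreading flow) and *inflated*
(entrywise power followed by column renormalization, sharpening flow)
until it converges to a sparse idempotent matrix whose attractor structure
defines the clusters.  The inflation exponent controls granularity; 2.0 is
the default used throughout.  The implementation is deterministic -- there
is no randomness anywhere in the procedure.

Clusters here are clusters of *links* (nodes of the hybrid graph); the
gene modules they induce are derived in :mod:`recolink.metrics`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph_core import Link
from .link_similarity import HybridGraph
from .metrics import EdgeCluster

logger = logging.getLogger(__name__)

#: above this many hybrid-graph nodes the iteration switches to sparse
#: matrices; below it dense arithmetic is used (results agree either way)
SPARSE_NODE_THRESHOLD = 5000

__all__ = ["MclConfig", "Clustering", "to_stochastic_matrix",
           "mcl_iterate", "extract_clusters", "cluster_hybrid_graph"]


@dataclass(frozen=True)
class MclConfig:
    """MCL tuning knobs.

    ``inflation`` (> 1) is the entrywise power of the inflate step;
    ``expansion`` the matrix power of the expand step; entries below
    ``prune_threshold`` are zeroed after each inflation, bounding the
    number of nonzeros a stochastic column can carry.  Self-loops of
    weight 1.0 are added before normalization by default, which damps the
    parity oscillations bipartite-like structures otherwise produce.
    """

    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-6
    max_iterations: int = 200
    convergence_tol: float = 1e-9
    add_self_loops: bool = True
    self_loop_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.inflation <= 1.0:
            raise ValueError(f"inflation must be > 1, got {self.inflation}")
        if self.expansion < 2:
            raise ValueError(f"expansion must be >= 2, got {self.expansion}")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")


@dataclass(frozen=True)
class Clustering:
    """A partition of the clustered links into mutually exclusive edge
    clusters, plus the link -> cluster-index map."""

    clusters: tuple
    assignments: dict = field(repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def to_stochastic_matrix(hg: HybridGraph, config: MclConfig):
    """Assemble the column-stochastic start matrix over ``hg.nodes``.

    Returns ``(matrix, nodes)`` where the matrix is dense below
    :data:`SPARSE_NODE_THRESHOLD` nodes and CSC sparse above.
    """
    nodes = hg.nodes
    n = len(nodes)
    if n == 0:
        raise ValueError("hybrid graph has no nodes")
    index = {link: i for i, link in enumerate(nodes)}
    use_sparse = n > SPARSE_NODE_THRESHOLD
    if use_sparse:
        rows, cols, vals = [], [], []
        for e1, e2, w in hg.weighted_edges:
            i, j = index[e1], index[e2]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        if config.add_self_loops:
            rows += list(range(n))
            cols += list(range(n))
            vals += [config.self_loop_weight] * n
        m = sp.csc_array((vals, (rows, cols)), shape=(n, n), dtype=float)
    else:
        m = np.zeros((n, n), dtype=float)
        for e1, e2, w in hg.weighted_edges:
            i, j = index[e1], index[e2]
            m[i, j] = w
            m[j, i] = w
        if config.add_self_loops:
            m[np.diag_indices(n)] += config.self_loop_weight
    m = _normalize_columns(m)
    return m, nodes


def _normalize_columns(m):
    """Rescale columns to sum to 1; an all-zero column (possible only with
    self-loops off and singleton nodes kept) becomes an identity column."""
    if sp.issparse(m):
        sums = np.asarray(m.sum(axis=0)).ravel()
        dead = np.flatnonzero(sums == 0)
        if dead.size:
            logger.warning("%d zero columns assigned identity", dead.size)
            m = m.tolil()
            for j in dead:
                m[j, j] = 1.0
            m = m.tocsc()
            sums = np.asarray(m.sum(axis=0)).ravel()
        d = sp.dia_array((1.0 / sums[None, :], [0]), shape=m.shape)
        return (m @ d).tocsc()
    sums = m.sum(axis=0)
    dead = np.flatnonzero(sums == 0)
    if dead.size:
        logger.warning("%d zero columns assigned identity", dead.size)
        m[dead, dead] = 1.0
        sums = m.sum(axis=0)
    return m / sums


def _inflate(m, power: float):
    if sp.issparse(m):
        m = m.copy()
        m.data = np.power(m.data, power)
        return m
    return np.power(m, power)


def _prune(m, threshold: float):
    if threshold <= 0:
        return m
    if sp.issparse(m):
        m = m.copy()
        m.data[m.data < threshold] = 0.0
        m.eliminate_zeros()
        return m
    m = m.copy()
    m[m < threshold] = 0.0
    return m


def _max_abs_diff(a, b) -> float:
    if sp.issparse(a):
        d = (a - b).tocoo()
        return float(np.max(np.abs(d.data))) if d.nnz else 0.0
    return float(np.max(np.abs(a - b)))


def mcl_iterate(matrix, config: MclConfig, check_stochastic: bool = False):
    """Run expand / inflate / prune rounds until the matrix stops moving.

    Convergence is a maximum absolute entrywise change below
    ``convergence_tol``; hitting ``max_iterations`` first returns the
    current matrix with a warning (clusters are still extracted from it).
    """
    m = matrix
    for it in range(config.max_iterations):
        prev = m
        m = m @ m if config.expansion == 2 else (
            np.linalg.matrix_power(m, config.expansion) if not sp.issparse(m)
            else _sparse_power(m, config.expansion))
        m = _inflate(m, config.inflation)
        m = _normalize_columns(m)
        m = _prune(m, config.prune_threshold)
        m = _normalize_columns(m)
        if check_stochastic:
            sums = (np.asarray(m.sum(axis=0)).ravel() if sp.issparse(m)
                    else m.sum(axis=0))
            assert np.allclose(sums, 1.0, atol=1e-9), "column sums drifted"
        if _max_abs_diff(m, prev) < config.convergence_tol:
            logger.debug("MCL converged after %d iterations", it + 1)
            return m
    logger.warning("MCL did not converge in %d iterations",
                   config.max_iterations)
    return m


def _sparse_power(m, k: int):
    out = m
    for _ in range(k - 1):
        out = out @ m
    return out


def extract_clusters(converged, nodes) -> Clustering:
    """Interpret a converged MCL matrix as a partition of ``nodes``.

    Attractors are nodes with positive diagonal mass; attractors with mass
    in each other's columns form one attractor system; every node joins
    the system of the attractor(s) with positive mass in its column.  A
    node attracted to several systems goes to the system containing the
    smallest node index, so the result is deterministic.  Clusters are
    sorted by size descending, ties by lexicographically smallest member.
    """
    n = len(nodes)
    if sp.issparse(converged):
        converged = sp.csc_array(converged)
        diag = converged.diagonal()
    else:
        diag = np.diag(converged)
    attractors = np.flatnonzero(diag > 0)

    parent = {int(a): int(a) for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    def column_support(j):
        if sp.issparse(converged):
            start, end = converged.indptr[j], converged.indptr[j + 1]
            return converged.indices[start:end][
                converged.data[start:end] > 0]
        return np.flatnonzero(converged[:, j] > 0)

    attractor_set = set(int(a) for a in attractors)
    for a in attractors:
        for i in column_support(int(a)):
            if int(i) in attractor_set:
                union(int(a), int(i))

    # system id = smallest attractor index in the system
    members: dict = {}
    for j in range(n):
        sys_ids = sorted({find(int(i)) for i in column_support(j)
                          if int(i) in attractor_set})
        if not sys_ids:
            # no attractor reaches this node (non-converged corner case):
            # it stands alone
            members.setdefault(("orphan", j), []).append(j)
        else:
            members.setdefault(("sys", sys_ids[0]), []).append(j)

    clusters = []
    for idxs in members.values():
        clusters.append(frozenset(nodes[i] for i in idxs))
    clusters.sort(key=lambda c: (-len(c), min(c)))
    edge_clusters = tuple(
        EdgeCluster(id=i, links=c) for i, c in enumerate(clusters)
    )
    assignments = {link: ec.id for ec in edge_clusters for link in ec.links}
    return Clustering(clusters=edge_clusters, assignments=assignments)


def cluster_hybrid_graph(hg: HybridGraph,
                         config: MclConfig | None = None) -> Clustering:
    """End-to-end MCL on a hybrid graph: matrix setup, iteration, cluster
    extraction.  An empty hybrid graph yields an empty clustering."""
    config = config or MclConfig()
    if hg.n_nodes == 0:
        return Clustering(clusters=(), assignments={})
    m, nodes = to_stochastic_matrix(hg, config)
    converged = mcl_iterate(m, config)
    return extract_clusters(converged, nodes)
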