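"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written as plain exhaustive computation,
separate from the library's code paths: quadratic double loops over link
pairs, per-layer set scans, and a dense-matrix Markov-clustering reference
with naive cluster extraction from the rows of the limit matrix.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# link-similarity oracles (quadratic scans over explicit sets)
# ---------------------------------------------------------------------------

def brute_inclusive_neighbors(edge_set, gene):
    out = {gene}
    for (u, v) in edge_set:
        if u == gene:
            out.add(v)
        if v == gene:
            out.add(u)
    return out


def brute_topological_similarity(edge_set, e1, e2):
    shared = set(e1) & set(e2)
    if len(shared) != 1:
        return 0.0
    k = shared.pop()
    i = e1[0] if e1[1] == k else e1[1]
    j = e2[0] if e2[1] == k else e2[1]
    ni = brute_inclusive_neighbors(edge_set, i)
    nj = brute_inclusive_neighbors(edge_set, j)
    return len(ni & nj) / len(ni | nj)


def brute_attribute_similarity(occ_sets, e1, e2):
    a, b = occ_sets[e1], occ_sets[e2]
    return len(a & b) / len(a | b)


def brute_hybrid_edges(edge_set, occ_sets, alpha, beta, tol=1e-12):
    """All-pairs double loop over links; returns {frozenset({e1,e2}): S}."""
    links = sorted(edge_set)
    out = {}
    for e1, e2 in itertools.combinations(links, 2):
        st = brute_topological_similarity(edge_set, e1, e2)
        if len(set(e1) & set(e2)) != 1:
            continue
        sa = brute_attribute_similarity(occ_sets, e1, e2)
        s = alpha * st + (1 - alpha) * sa
        if s + tol >= beta:
            out[frozenset({e1, e2})] = s
    return out


# ---------------------------------------------------------------------------
# metric oracles (exhaustive scans)
# ---------------------------------------------------------------------------

def brute_gamma_support(cluster_links, layer_edge_sets, gamma):
    need = math.ceil(round(gamma * len(cluster_links), 9))
    return sum(
        1 for layer in layer_edge_sets
        if len(set(cluster_links) & set(layer)) >= need
    )


def brute_induced_edge_count(cluster_links, summary_links):
    genes = {g for e in cluster_links for g in e}
    return sum(1 for (u, v) in summary_links if u in genes and v in genes)


# ---------------------------------------------------------------------------
# dense Markov-clustering reference
# ---------------------------------------------------------------------------

def reference_mcl(n, weighted_edges, inflation=2.0, loop_weight=1.0,
                  prune=1e-6, tol=1e-9, max_iter=200):
    """Dense 64-bit MCL over nodes 0..n-1.

    ``weighted_edges`` is a list of (i, j, w).  Returns a list of frozensets
    of node indices (the clusters), extracted from the rows of the limit
    matrix and merged when they overlap.
    """
    m = np.zeros((n, n))
    for i, j, w in weighted_edges:
        m[i, j] = w
        m[j, i] = w
    for i in range(n):
        m[i, i] += loop_weight
    m = m / m.sum(axis=0)
    for _ in range(max_iter):
        prev = m.copy()
        m = m @ m
        m = m ** inflation
        m = m / m.sum(axis=0)
        m[m < prune] = 0.0
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < tol:
            break
    # rows of attractors list their cluster members
    raw = []
    for i in range(n):
        if m[i, i] > 0:
            raw.append(set(np.flatnonzero(m[i, :] > 0).tolist()) | {i})
    merged: list = []
    for c in raw:
        hit = [g for g in merged if g & c]
        for g in hit:
            merged.remove(g)
            c = c | g
        merged.append(c)
    covered = set().union(*merged) if merged else set()
    for i in range(n):
        if i not in covered:
            merged.append({i})
    return [frozenset(c) for c in merged]
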