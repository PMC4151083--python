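"""Shared fixtures: small deterministic graphs and random multi-layer
generators used across the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from recolink.graph_core import (LayerGraph, Link, MultiLayerGraph,
                                 build_summary_graph)


def make_mlg(layer_edge_sets, genes=None):
    """Build a MultiLayerGraph from a list of iterable-of-pairs."""
    layers = [
        LayerGraph(layer_id=f"L{j}",
                   edges=frozenset(Link(u, v) for u, v in edges))
        for j, edges in enumerate(layer_edge_sets)
    ]
    return MultiLayerGraph.from_layers(layers, genes=genes)


def random_mlg(rng, n_genes=20, n_layers=5, p=0.15):
    """Random unweighted layers over a shared universe (for oracle tests)."""
    genes = [f"g{i:02d}" for i in range(n_genes)]
    pairs = list(itertools.combinations(genes, 2))
    layer_sets = []
    for _ in range(n_layers):
        mask = rng.random(len(pairs)) < p
        layer_sets.append([p_ for p_, hit in zip(pairs, mask) if hit])
    return make_mlg(layer_sets, genes=genes)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def neighborhood_summary():
    """Single-layer summary over {a..g} realizing the 4/7 worked example:
    the non-shared endpoints b and d of links (a,b) and (a,d) have four
    common inclusive neighbors out of seven."""
    edges = [("a", "b"), ("a", "d"), ("b", "c"), ("b", "d"), ("b", "e"),
             ("c", "d"), ("d", "f"), ("d", "g")]
    return build_summary_graph(make_mlg([edges]))


@pytest.fixture
def occurrence_summary():
    """Six layers in which link (a,b) occurs in layers 0-4 and link (a,d)
    in layers 1-5 (the 4-of-6 occurrence-overlap worked example)."""
    e1, e2 = ("a", "b"), ("a", "d")
    layer_sets = []
    for j in range(6):
        edges = []
        if j <= 4:
            edges.append(e1)
        if j >= 1:
            edges.append(e2)
        layer_sets.append(edges)
    return build_summary_graph(make_mlg(layer_sets, genes=["a", "b", "d"]))
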