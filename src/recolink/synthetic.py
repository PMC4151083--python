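"""Synthetic multi-layer graphs with planted recurrent modules.

The generator plants gene modules that recur across layers: in each of a
module's active layers, every within-module gene pair is present with a
high probability, on top of sparse independent background edges everywhere.
This emulates the target signal of recurrent-module mining -- sets of
coexpression links that co-occur across datasets -- without modelling
expression-level noise.  A matched randomization keeps each layer's node
and edge counts but resamples the edges uniformly, which destroys the
co-occurrence structure and serves as the negative control.

All randomness flows from a single seed: per-layer and per-module streams
are split off deterministically with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph_core import LayerGraph, Link, MultiLayerGraph

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedModule",
    "PlantedSpec",
    "ModuleTruth",
    "GroundTruth",
    "generate_planted",
    "default_planted_spec",
    "generate_matched_random",
    "recovery_score",
    "write_ground_truth",
]


@dataclass(frozen=True)
class PlantedModule:
    """One planted module: its gene set, within-module edge probability in
    an active layer, and the number of layers it is active in."""

    genes: frozenset
    within_prob: float = 0.9
    recurrence: int = 8

    def __post_init__(self) -> None:
        if len(self.genes) < 4:
            raise ValueError("a planted module needs at least 4 genes")
        if not (0.0 < self.within_prob <= 1.0):
            raise ValueError("within_prob must be in (0, 1]")


@dataclass(frozen=True)
class PlantedSpec:
    """Generator parameters: universe size, layer count, background edge
    probability, the planted modules (gene sets may overlap), and the seed."""

    n_genes: int = 60
    n_layers: int = 10
    background_edge_prob: float = 0.01
    modules: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_layers < 1:
            raise ValueError("need at least 2 genes and 1 layer")
        if not (0.0 <= self.background_edge_prob < 1.0):
            raise ValueError("background_edge_prob must be in [0, 1)")
        for mod in self.modules:
            if mod.recurrence > self.n_layers:
                raise ValueError("module recurrence exceeds the layer count")

    def gene_labels(self) -> tuple:
        width = len(str(self.n_genes - 1))
        return tuple(f"g{i:0{width}d}" for i in range(self.n_genes))


@dataclass(frozen=True)
class ModuleTruth:
    genes: frozenset
    links: frozenset  # every within-module pair (the planted clique)
    active_layers: tuple  # 0-based layer indices


@dataclass(frozen=True)
class GroundTruth:
    modules: tuple
    spec: PlantedSpec


def default_planted_spec(seed: int = 0) -> PlantedSpec:
    """The stock benchmark: 60 genes, 10 layers, 1% background, and two
    disjoint 6-gene modules with within-module edge probability 0.9 active
    in 8 of the 10 layers."""
    labels = [f"g{i:02d}" for i in range(60)]
    return PlantedSpec(
        n_genes=60,
        n_layers=10,
        background_edge_prob=0.01,
        modules=(
            PlantedModule(genes=frozenset(labels[0:6]),
                          within_prob=0.9, recurrence=8),
            PlantedModule(genes=frozenset(labels[6:12]),
                          within_prob=0.9, recurrence=8),
        ),
        seed=seed,
    )


def _all_pairs(genes) -> list:
    return [Link(u, v) for u, v in itertools.combinations(sorted(genes), 2)]


def generate_planted(spec: PlantedSpec) -> tuple:
    """Generate a multi-layer graph with planted recurrent modules.

    Per layer, every gene pair is a background edge with
    ``background_edge_prob``; additionally, for each module active in that
    layer, every within-module pair is present with ``within_prob``.
    Deterministic for a fixed spec (including its seed).
    """
    genes = spec.gene_labels()
    ss = np.random.SeedSequence(spec.seed)
    layer_ss, module_ss = ss.spawn(2)
    layer_streams = [np.random.default_rng(s)
                     for s in layer_ss.spawn(spec.n_layers)]
    module_rng = np.random.default_rng(module_ss)

    expected_density = spec.background_edge_prob
    if spec.modules:
        expected_density += max(m.within_prob for m in spec.modules)
    if expected_density >= 1.0 and spec.background_edge_prob > 0.5:
        logger.warning("spec is over-dense; the summary graph will be "
                       "nearly complete")

    truths = []
    active_by_layer: dict = {j: [] for j in range(spec.n_layers)}
    for mod in spec.modules:
        active = np.sort(module_rng.choice(
            spec.n_layers, size=mod.recurrence, replace=False))
        clique = frozenset(_all_pairs(mod.genes))
        truths.append(ModuleTruth(genes=frozenset(mod.genes), links=clique,
                                  active_layers=tuple(int(a) for a in active)))
        for j in active:
            active_by_layer[int(j)].append(mod)

    pairs = _all_pairs(genes)
    layers = []
    for j in range(spec.n_layers):
        rng = layer_streams[j]
        mask = rng.random(len(pairs)) < spec.background_edge_prob
        edges = {p for p, hit in zip(pairs, mask) if hit}
        for mod in active_by_layer[j]:
            mpairs = _all_pairs(mod.genes)
            mmask = rng.random(len(mpairs)) < mod.within_prob
            edges |= {p for p, hit in zip(mpairs, mmask) if hit}
        layers.append(LayerGraph(layer_id=f"layer{j:02d}",
                                 edges=frozenset(edges)))
    mlg = MultiLayerGraph(genes=genes, layers=tuple(layers))
    return mlg, GroundTruth(modules=tuple(truths), spec=spec)


def generate_matched_random(mlg: MultiLayerGraph, seed: int) -> MultiLayerGraph:
    """Resample each layer as a uniform random edge set with exactly the
    same node count and edge count; degree sequences are not preserved."""
    pairs = _all_pairs(mlg.genes)
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(mlg.n_layers)]
    layers = []
    for lay, rng in zip(mlg.layers, streams):
        m = len(lay.edges)
        if m > len(pairs):
            raise ValueError(f"layer {lay.layer_id!r} has more edges than "
                             "gene pairs")
        chosen = rng.choice(len(pairs), size=m, replace=False)
        layers.append(LayerGraph(
            layer_id=lay.layer_id,
            edges=frozenset(pairs[i] for i in chosen)))
    return MultiLayerGraph(genes=mlg.genes, layers=tuple(layers))


def recovery_score(found_modules, truth: GroundTruth) -> list:
    """Best gene-set Jaccard against each planted module.

    Returns one score per planted module: the maximum, over the found
    modules, of ``|found ∩ planted| / |found ∪ planted|``; zero when
    nothing was found.  Order-independent in both arguments.
    """
    found = [frozenset(m) for m in found_modules]
    scores = []
    for mod in truth.modules:
        best = 0.0
        for f in found:
            if not f:
                continue
            j = len(f & mod.genes) / len(f | mod.genes)
            best = max(best, j)
        scores.append(best)
    return scores


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """JSON sidecar with the planted gene sets, active layers, and the
    generator parameters."""
    payload = {
        "spec": {
            "n_genes": truth.spec.n_genes,
            "n_layers": truth.spec.n_layers,
            "background_edge_prob": truth.spec.background_edge_prob,
            "seed": truth.spec.seed,
            "modules": [
                {"genes": sorted(m.genes), "within_prob": m.within_prob,
                 "recurrence": m.recurrence}
                for m in truth.spec.modules
            ],
        },
        "modules": [
            {"genes": sorted(m.genes),
             "links": [l.name() for l in sorted(m.links)],
             "active_layers": list(m.active_layers)}
            for m in truth.modules
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
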