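"""Multi-layer graphs and the edge-attributed summary graph.

A *multi-layer graph* is a collection of simple undirected graphs (layers)
over one shared gene universe -- one layer per expression dataset.  The
*summary graph* is the union of all layer edge sets, where each link carries
a binary occurrence vector recording the layers it appears in.  Links that
occur in too few layers can be pruned by a minimum edge-frequency threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Link",
    "LayerGraph",
    "MultiLayerGraph",
    "SummaryGraph",
    "build_summary_graph",
    "edge_frequency",
    "prune_by_frequency",
    "read_edge_list",
    "write_edge_list",
    "write_summary_tsv",
    "read_summary_tsv",
]


def _check_gene_label(label: str) -> str:
    if not isinstance(label, str) or not label:
        raise ValueError(f"gene label must be a non-empty string, got {label!r}")
    if any(c.isspace() for c in label):
        raise ValueError(f"gene label may not contain whitespace: {label!r}")
    return label


class Link(tuple):
    """An undirected gene pair, stored canonically with ``u < v``.

    Equality and hashing are on the canonical pair, so ``Link("b", "a")``
    and ``Link("a", "b")`` are the same object value.  Self-loops are
    rejected.
    """

    __slots__ = ()

    def __new__(cls, u: str, v: str) -> "Link":
        _check_gene_label(u)
        _check_gene_label(v)
        if u == v:
            raise ValueError(f"self-loop not allowed: ({u!r}, {v!r})")
        if v < u:
            u, v = v, u
        return tuple.__new__(cls, (u, v))

    @property
    def u(self) -> str:
        return self[0]

    @property
    def v(self) -> str:
        return self[1]

    def name(self) -> str:
        """Canonical ``u|v`` label used in link-graph file formats."""
        return f"{self[0]}|{self[1]}"

    @classmethod
    def parse(cls, name: str) -> "Link":
        u, sep, v = name.partition("|")
        if not sep:
            raise ValueError(f"cannot parse link name {name!r} (expected 'u|v')")
        return cls(u, v)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Link({self[0]!r}, {self[1]!r})"


@dataclass(frozen=True)
class LayerGraph:
    """One unweighted graph layer: an edge set tagged with a layer id."""

    layer_id: str
    edges: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(
            e if isinstance(e, Link) else Link(*e) for e in self.edges
        ))

    def genes(self) -> frozenset:
        return frozenset(g for e in self.edges for g in e)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class MultiLayerGraph:
    """``d`` graph layers over one shared, ordered gene universe."""

    genes: tuple
    layers: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) < 1:
            raise ValueError("a multi-layer graph needs at least one layer")
        ids = [lay.layer_id for lay in self.layers]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate layer ids: {ids}")
        universe = set(self.genes)
        if len(universe) != len(self.genes):
            raise ValueError("duplicate genes in universe")
        for lay in self.layers:
            missing = lay.genes() - universe
            if missing:
                raise ValueError(
                    f"layer {lay.layer_id!r} uses genes outside the universe: "
                    f"{sorted(missing)[:5]}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def layer_ids(self) -> tuple:
        return tuple(lay.layer_id for lay in self.layers)

    @classmethod
    def from_layers(
        cls, layers: Iterable[LayerGraph], genes: Iterable[str] | None = None
    ) -> "MultiLayerGraph":
        """Assemble a multi-layer graph; the universe defaults to the union
        of genes seen in any layer (isolated genes may be added explicitly)."""
        layers = tuple(layers)
        if genes is None:
            universe: set = set()
            for lay in layers:
                universe |= lay.genes()
            genes = sorted(universe)
        else:
            genes = sorted(set(genes))
        return cls(genes=tuple(genes), layers=layers)


@dataclass(frozen=True)
class SummaryGraph:
    """Edge-attributed union of the layers.

    ``links`` is the sorted union edge set; ``occurrence`` is a binary
    |links| x d matrix whose (i, j) entry says whether link i appears in
    layer j; ``adjacency`` maps each gene to its neighbor set.
    """

    genes: tuple
    links: tuple
    occurrence: np.ndarray
    layer_ids: tuple
    adjacency: Mapping[str, frozenset] = field(repr=False, default=None)
    _index: Mapping[Link, int] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.adjacency is None:
            adj: dict = {g: set() for g in self.genes}
            for link in self.links:
                adj[link.u].add(link.v)
                adj[link.v].add(link.u)
            object.__setattr__(
                self, "adjacency", {g: frozenset(s) for g, s in adj.items()}
            )
        if self._index is None:
            object.__setattr__(
                self, "_index", {link: i for i, link in enumerate(self.links)}
            )
        occ = np.asarray(self.occurrence, dtype=np.int8)
        if occ.shape != (len(self.links), len(self.layer_ids)):
            raise ValueError(
                f"occurrence matrix shape {occ.shape} does not match "
                f"{len(self.links)} links x {len(self.layer_ids)} layers"
            )
        object.__setattr__(self, "occurrence", occ)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def n_layers(self) -> int:
        return len(self.layer_ids)

    def link_index(self, link: Link) -> int:
        try:
            return self._index[link]
        except KeyError:
            raise KeyError(f"link {link.name()} not in summary graph") from None

    def __contains__(self, link: Link) -> bool:
        return link in self._index

    def occurrence_set(self, link: Link) -> frozenset:
        """Indices of the layers a link occurs in (0-based columns)."""
        row = self.occurrence[self.link_index(link)]
        return frozenset(np.flatnonzero(row).tolist())

    def neighbors(self, gene: str) -> frozenset:
        try:
            return self.adjacency[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in summary graph") from None

    def to_layers(self) -> MultiLayerGraph:
        """Split the occurrence columns back into per-layer edge sets."""
        layers = []
        for j, lid in enumerate(self.layer_ids):
            members = frozenset(
                self.links[i] for i in np.flatnonzero(self.occurrence[:, j])
            )
            layers.append(LayerGraph(layer_id=lid, edges=members))
        return MultiLayerGraph(genes=self.genes, layers=tuple(layers))


def build_summary_graph(mlg: MultiLayerGraph) -> SummaryGraph:
    """Union the layer edge sets into an edge-attributed summary graph.

    Links are sorted canonically by ``(u, v)`` and the occurrence matrix has
    one column per layer, in layer order.
    """
    if mlg.n_layers == 0:
        raise ValueError("cannot summarize a multi-layer graph with no layers")
    union: set = set()
    for lay in mlg.layers:
        union |= lay.edges
    links = tuple(sorted(union))
    occ = np.zeros((len(links), mlg.n_layers), dtype=np.int8)
    index = {link: i for i, link in enumerate(links)}
    for j, lay in enumerate(mlg.layers):
        for e in lay.edges:
            occ[index[e], j] = 1
    return SummaryGraph(
        genes=mlg.genes, links=links, occurrence=occ, layer_ids=mlg.layer_ids
    )


def edge_frequency(summary: SummaryGraph, link: Link) -> int:
    """Number of layers a link occurs in (its row sum in the occurrence
    matrix)."""
    return int(summary.occurrence[summary.link_index(link)].sum())


def prune_by_frequency(summary: SummaryGraph, min_freq: int) -> SummaryGraph:
    """Keep only links occurring in at least ``min_freq`` layers (inclusive).

    Genes left with no incident link are dropped from the vertex set; the
    layer columns are unchanged.  A threshold no link reaches yields an
    empty summary graph (with a warning), not an error.
    """
    if min_freq < 1:
        raise ValueError(f"min_freq must be >= 1, got {min_freq}")
    freqs = summary.occurrence.sum(axis=1)
    keep = np.flatnonzero(freqs >= min_freq)
    if keep.size == 0:
        logger.warning(
            "prune_by_frequency(min_freq=%d) removed every link", min_freq
        )
    links = tuple(summary.links[i] for i in keep)
    occ = summary.occurrence[keep, :]
    surviving_genes = {g for link in links for g in link}
    genes = tuple(g for g in summary.genes if g in surviving_genes)
    return SummaryGraph(
        genes=genes, links=links, occurrence=occ, layer_ids=summary.layer_ids
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, layer_id: str | None = None) -> LayerGraph:
    """Read a two-column TSV edge list (``#`` lines are comments).

    Duplicate edges collapse; the layer id defaults to the filename stem.
    """
    path = Path(path)
    if layer_id is None:
        layer_id = path.stem
        if layer_id.endswith(".edges"):  # our own "<id>.edges.tsv" outputs
            layer_id = layer_id[: -len(".edges")]
    edges: set = set()
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two tab-separated columns")
            edges.add(Link(parts[0], parts[1]))
    return LayerGraph(layer_id=layer_id, edges=frozenset(edges))


def write_edge_list(layer: LayerGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for link in sorted(layer.edges):
            fh.write(f"{link.u}\t{link.v}\n")


def write_summary_tsv(summary: SummaryGraph, path: str | Path,
                      header_comment: str | None = None) -> None:
    """Write ``gene_u  gene_v  frequency  layer_ids`` rows in canonical
    order (sorted by (u, v)); layer_ids are comma-separated."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("# gene_u\tgene_v\tfrequency\tlayer_ids\n")
        for i, link in enumerate(summary.links):
            cols = np.flatnonzero(summary.occurrence[i])
            lids = ",".join(summary.layer_ids[j] for j in cols)
            fh.write(f"{link.u}\t{link.v}\t{len(cols)}\t{lids}\n")


def read_summary_tsv(path: str | Path,
                     layer_ids: Sequence[str]) -> SummaryGraph:
    """Read a summary TSV written by :func:`write_summary_tsv`.

    The full ordered layer-id list must be supplied because rows only name
    the layers each link occurs in.
    """
    layer_ids = tuple(layer_ids)
    col = {lid: j for j, lid in enumerate(layer_ids)}
    links: list = []
    rows: list = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns")
            link = Link(parts[0], parts[1])
            row = np.zeros(len(layer_ids), dtype=np.int8)
            for lid in parts[3].split(","):
                row[col[lid]] = 1
            if int(parts[2]) != int(row.sum()):
                raise ValueError(f"{path}:{ln}: frequency column disagrees "
                                 "with layer_ids column")
            links.append(link)
            rows.append(row)
    order = sorted(range(len(links)), key=lambda i: links[i])
    links = [links[i] for i in order]
    occ = (np.vstack([rows[i] for i in order]) if links
           else np.zeros((0, len(layer_ids)), dtype=np.int8))
    genes = tuple(sorted({g for link in links for g in link}))
    return SummaryGraph(genes=genes, links=tuple(links), occurrence=occ,
                        layer_ids=layer_ids)
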