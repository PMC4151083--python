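"""Module derivation and the RE / density / γ-support statistics."""

import numpy as np
import pytest

from conftest import make_mlg, random_mlg
from oracles import brute_gamma_support, brute_induced_edge_count
from recolink.graph_core import Link, build_summary_graph, edge_frequency
from recolink.mcl import Clustering
from recolink.metrics import (EdgeCluster, cluster_density, cluster_table,
                              compute_cluster_metrics, edge_ratio,
                              export_gene_sets, gamma_support,
                              module_vertices, summarize_clusters)


def ec(pairs, id=0):
    return EdgeCluster(id=id, links=frozenset(Link(u, v) for u, v in pairs))


def make_clustering(*clusters):
    ecs = tuple(ec(pairs, id=i) for i, pairs in enumerate(clusters))
    return Clustering(
        clusters=ecs,
        assignments={l: e.id for e in ecs for l in e.links})


class TestModuleVertices:
    def test_endpoint_union(self):
        got = module_vertices(ec([("a", "b"), ("b", "c"), ("c", "d"),
                                  ("d", "e")]))
        assert got == {"a", "b", "c", "d", "e"}

    def test_link_partition_still_overlaps_in_genes(self):
        m1 = module_vertices(ec([("a", "b")]))
        m2 = module_vertices(ec([("b", "c")], id=1))
        assert m1 & m2 == {"b"}

    def test_matches_exhaustive_scan(self, rng):
        s = build_summary_graph(random_mlg(rng, n_genes=15, n_layers=3))
        links = list(s.links)[:8]
        cluster = EdgeCluster(id=0, links=frozenset(links))
        expected = set()
        for l in links:
            expected.add(l.u)
            expected.add(l.v)
        assert module_vertices(cluster) == expected


class TestEdgeRatio:
    def test_full_induced_set_is_one(self):
        s = build_summary_graph(make_mlg([[("a", "b"), ("b", "c")]]))
        assert edge_ratio(ec([("a", "b"), ("b", "c")]), s) == 1.0

    def test_half_of_induced_links(self):
        # induced subgraph on {a,b,c,d} has 6 links; the cluster holds 3
        all_six = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"),
                   ("b", "d"), ("c", "d")]
        s = build_summary_graph(make_mlg([all_six]))
        assert edge_ratio(ec(all_six[:3]), s) == 0.5

    def test_matches_brute_force_induced_count(self, rng):
        s = build_summary_graph(random_mlg(rng, n_genes=15, n_layers=4))
        links = list(s.links)[: max(4, s.n_links // 3)]
        cluster = EdgeCluster(id=0, links=frozenset(links))
        pairs = [(l.u, l.v) for l in links]
        summary_pairs = [(l.u, l.v) for l in s.links]
        want = len(links) / brute_induced_edge_count(pairs, summary_pairs)
        assert edge_ratio(cluster, s) == pytest.approx(want, abs=1e-15)

    def test_strictly_below_one_when_induced_link_missing(self):
        triangle = [("a", "b"), ("b", "c"), ("a", "c")]
        s = build_summary_graph(make_mlg([triangle]))
        assert edge_ratio(ec(triangle[:2]), s) < 1.0


class TestClusterDensity:
    @pytest.mark.parametrize("pairs,expected", [
        ([("a", "b"), ("b", "c"), ("a", "c")], 1.0),                # clique
        ([("a", "b"), ("a", "c"), ("a", "d")], 0.5),                # star
        ([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")], 0.4),    # path
    ], ids=["triangle", "star", "path"])
    def test_formula(self, pairs, expected):
        assert cluster_density(ec(pairs)) == pytest.approx(expected)

    def test_uses_cluster_links_not_induced_count(self):
        """Density must count |EC| itself, not the induced summary links
        (guards against the wrong variant that substitutes the induced
        edge count)."""
        triangle = [("a", "b"), ("b", "c"), ("a", "c")]
        s = build_summary_graph(make_mlg([triangle]))
        cluster = ec(triangle[:2])  # 2 of 3 induced links
        assert cluster_density(cluster) == pytest.approx(2 * 2 / (3 * 2))
        wrong_variant = 2 * 3 / (3 * 2)  # would be 1.0
        assert cluster_density(cluster) != wrong_variant


class TestGammaSupport:
    def test_conventional_support_at_gamma_one(self):
        four = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        layers = [four, four, four, four[:2], []]
        mlg = make_mlg(layers)
        assert gamma_support(ec(four), mlg, 1.0) == 3

    def test_ceiling_boundary(self):
        four = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        mlg = make_mlg([four[:2]])  # layer holds 2 of the 4 links
        cluster = ec(four)
        assert gamma_support(cluster, mlg, 0.5) == 1   # need ceil(2) = 2
        assert gamma_support(cluster, mlg, 0.75) == 0  # need ceil(3) = 3

    @pytest.mark.parametrize("gamma", [0.5, 0.75, 1.0])
    def test_matches_brute_force_layer_scan(self, rng, gamma):
        mlg = random_mlg(rng, n_genes=12, n_layers=6, p=0.2)
        s = build_summary_graph(mlg)
        links = list(s.links)[:6]
        cluster = EdgeCluster(id=0, links=frozenset(links))
        layer_sets = [{(l.u, l.v) for l in lay.edges} for lay in mlg.layers]
        want = brute_gamma_support([(l.u, l.v) for l in links],
                                   layer_sets, gamma)
        assert gamma_support(cluster, mlg, gamma) == want
        # the vectorized occurrence-matrix route agrees with the layer scan
        cm = compute_cluster_metrics(cluster, s, gammas=(gamma,))
        assert cm.gamma_supports[gamma] == want

    def test_non_increasing_in_gamma(self, rng):
        mlg = random_mlg(rng, n_genes=12, n_layers=6, p=0.25)
        s = build_summary_graph(mlg)
        links = list(s.links)[:8]
        cluster = EdgeCluster(id=0, links=frozenset(links))
        sups = [gamma_support(cluster, mlg, g)
                for g in (0.25, 0.5, 0.75, 1.0)]
        assert sups == sorted(sups, reverse=True)

    def test_bounded_by_rarest_link_frequency(self, rng):
        mlg = random_mlg(rng, n_genes=12, n_layers=6, p=0.25)
        s = build_summary_graph(mlg)
        links = list(s.links)[:5]
        cluster = EdgeCluster(id=0, links=frozenset(links))
        rarest = min(edge_frequency(s, l) for l in links)
        assert gamma_support(cluster, mlg, 1.0) <= rarest


class TestSummarizeClusters:
    def test_means_over_two_clusters(self):
        pairs4 = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        pairs6 = [("p", "q"), ("q", "r"), ("r", "s"), ("s", "t"),
                  ("t", "u"), ("u", "v")]
        mlg = make_mlg([pairs4 + pairs6] * 5)
        s = build_summary_graph(mlg)
        clustering = make_clustering(pairs4, pairs6)
        row = summarize_clusters(clustering, s, mlg).iloc[0]
        assert row["n_clusters"] == 2
        assert row["mean_links"] == 5.0
        assert row["mean_sup_1"] == 5.0
        assert row["pct_frequent_1"] == 100

    def test_all_below_min_size_gives_empty_row(self):
        mlg = make_mlg([[("a", "b"), ("b", "c")]])
        s = build_summary_graph(mlg)
        clustering = make_clustering([("a", "b"), ("b", "c")])
        row = summarize_clusters(clustering, s, mlg,
                                 min_cluster_links=4).iloc[0]
        assert row["n_clusters"] == 0

    def test_aggregation_equals_per_cluster_recomputation(self, rng):
        mlg = random_mlg(rng, n_genes=14, n_layers=5, p=0.25)
        s = build_summary_graph(mlg)
        links = list(s.links)
        clustering = make_clustering(
            [(l.u, l.v) for l in links[:5]],
            [(l.u, l.v) for l in links[5:11]],
        )
        row = summarize_clusters(clustering, s, mlg).iloc[0]
        metrics = [compute_cluster_metrics(e, s) for e in clustering.clusters]
        assert row["mean_RE"] == pytest.approx(
            np.mean([m.edge_ratio for m in metrics]))
        assert row["mean_density"] == pytest.approx(
            np.mean([m.density for m in metrics]))
        assert row["mean_sup_0.5"] == pytest.approx(
            np.mean([m.gamma_supports[0.5] for m in metrics]))


class TestExportGeneSets:
    def test_min_gene_filter_and_gmt_shape(self, tmp_path):
        small = [("a", "b"), ("b", "c")]  # 3 genes: excluded at min 5
        big = [("p", "q"), ("q", "r"), ("r", "s"), ("s", "t"), ("t", "u"),
               ("u", "v"), ("v", "w")]  # 8 genes
        clustering = make_clustering(small, big)
        path = tmp_path / "modules.gmt"
        n = export_gene_sets(clustering, path, min_genes=5)
        assert n == 1
        lines = path.read_text().strip().split("\n")
        fields = lines[0].split("\t")
        assert fields[0] == "module_1"
        assert len(fields) == 2 + 8

    def test_count_equals_brute_force_filter(self, rng, tmp_path):
        mlg = random_mlg(rng, n_genes=20, n_layers=3, p=0.15)
        s = build_summary_graph(mlg)
        links = list(s.links)
        chunks = [links[i:i + 4] for i in range(0, min(len(links), 24), 4)]
        clustering = make_clustering(
            *[[(l.u, l.v) for l in c] for c in chunks if c])
        n = export_gene_sets(clustering, tmp_path / "m.gmt", min_genes=5)
        want = sum(1 for e in clustering.clusters
                   if len(module_vertices(e)) >= 5)
        assert n == want


def test_cluster_table_columns_and_order(rng):
    mlg = random_mlg(rng, n_genes=14, n_layers=5, p=0.3)
    s = build_summary_graph(mlg)
    links = list(s.links)
    clustering = make_clustering([(l.u, l.v) for l in links[:5]],
                                 [(l.u, l.v) for l in links[5:9]])
    table = cluster_table(clustering, s)
    assert list(table.columns) == [
        "cluster_id", "n_links", "n_genes", "RE", "density",
        "sup_0.5", "sup_0.75", "sup_1", "genes", "links"]
    for genes in table["genes"]:
        parts = genes.split(",")
        assert parts == sorted(parts)
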