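import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import make_callset, make_metadata
from ctcna.enrichment import (
    EnrichmentResult,
    GeneSetCollection,
    build_term_network,
    enrich_cell,
    export_network,
    genes_in_calls,
    hypergeometric_enrich,
    read_gmt,
    write_gmt,
)


@pytest.fixture()
def two_gene_annotation():
    return pd.DataFrame(
        {
            "gene": ["g1", "g2"],
            "chrom": ["chr1", "chr1"],
            "start": [100_000, 900_000],
            "end": [200_000, 1_100_000],
        }
    )


class TestGenesInCalls:
    def test_overlap_vs_containment(self, two_gene_annotation):
        cs = make_callset("c", [("chr1", 0, 1_000_000, 3)])
        assert genes_in_calls(cs, two_gene_annotation, "any_overlap") == {"g1", "g2"}
        assert genes_in_calls(cs, two_gene_annotation, "contained") == {"g1"}

    def test_empty_calls_empty_set(self, two_gene_annotation):
        assert genes_in_calls(make_callset("c", []), two_gene_annotation) == frozenset()

    def test_whole_genome_call_collects_all_genes(self, two_gene_annotation):
        cs = make_callset("c", [("chr1", 0, 10_000_000, 1)])
        assert genes_in_calls(cs, two_gene_annotation) == {"g1", "g2"}


class TestHypergeometricEnrich:
    def collection(self):
        universe = frozenset(f"g{i}" for i in range(10))
        return GeneSetCollection(sets=[("T1", "term one", frozenset({"g1", "g2", "g3", "g4", "g5"}))], universe=universe)

    def test_worked_example(self):
        out = hypergeometric_enrich(frozenset({"g1", "g2"}), self.collection())
        assert out == [("T1", 2, pytest.approx(10 / 45))]

    def test_zero_overlap_p_is_one(self):
        out = hypergeometric_enrich(frozenset({"g6", "g7"}), self.collection())
        assert out[0][2] == 1.0

    def test_query_equals_universe_p_one(self):
        universe = frozenset({"g1", "g2"})
        coll = GeneSetCollection(sets=[("T", "t", universe)], universe=universe)
        assert hypergeometric_enrich(universe, coll)[0][2] == 1.0

    def test_outside_universe_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            out = hypergeometric_enrich(frozenset({"g1", "zz"}), self.collection())
        assert out[0][1] == 1

    def test_empty_query_warns_empty_result(self):
        with pytest.warns(UserWarning, match="empty"):
            assert hypergeometric_enrich(frozenset(), self.collection()) == []


class TestEnrichCell:
    def test_no_calls_empty_result(self, two_gene_annotation):
        coll = GeneSetCollection(sets=[("T", "t", frozenset({"g1"}))], universe=frozenset({"g1", "g2"}))
        res = enrich_cell(make_callset("c", []), two_gene_annotation, coll)
        assert res.rows == []

    def test_constructed_term_strongly_enriched(self):
        """1,000-gene universe, a 30-gene term whose genes are exactly the
        cell's aberrant genes: retained with adjusted p below 1e-6."""
        genes = [f"g{i:04d}" for i in range(1000)]
        ann = pd.DataFrame(
            {
                "gene": genes,
                "chrom": "chr1",
                "start": np.arange(1000) * 10_000,
                "end": np.arange(1000) * 10_000 + 5_000,
            }
        )
        term = frozenset(genes[:30])
        other = frozenset(genes[500:540])
        coll = GeneSetCollection(
            sets=[("T_hit", "hit", term), ("T_other", "other", other)], universe=frozenset(genes)
        )
        cs = make_callset("c", [("chr1", 0, 30 * 10_000 - 5_000, 4)])
        res = enrich_cell(cs, ann, coll)
        assert [r["term_id"] for r in res.rows] == ["T_hit"]
        assert res.rows[0]["p_adj"] < 1e-6
        assert res.rows[0]["overlap_genes"] == term
        assert res.rows[0]["p_adj"] >= res.rows[0]["p"]

    def test_filter_keeps_only_adjusted_significant(self, two_gene_annotation):
        coll = GeneSetCollection(
            sets=[("T", "t", frozenset({"g1", "g2"}))], universe=frozenset({"g1", "g2"})
        )
        cs = make_callset("c", [("chr1", 0, 2_000_000, 3)])
        res = enrich_cell(cs, two_gene_annotation, coll)  # p = 1: filtered
        assert res.rows == []


def result(cell_id, term_rows):
    return EnrichmentResult(
        cell_id=cell_id,
        rows=[
            {"term_id": t, "term_name": t, "overlap": len(g), "p": 1e-8, "p_adj": 1e-6, "overlap_genes": frozenset(g)}
            for t, g in term_rows
        ],
    )


class TestNetwork:
    meta = make_metadata(
        [
            ("a1", "p", "A", "relapsed", "CTC"),
            ("a2", "p", "A", "relapsed", "CTC"),
            ("b1", "p", "B", "relapsed", "CTC"),
            ("b2", "p", "B", "relapsed", "CTC"),
        ]
    )

    def test_strict_edge_threshold(self):
        g11 = [f"x{i}" for i in range(11)]
        g10 = g11[:10]
        res = [result("a1", [("T1", g11), ("T2", g11)]), result("a2", [("T3", g10), ("T4", g10)])]
        net = build_term_network(res, self.meta)
        edges = {(a, b) for a, b, _ in net.edges}
        assert ("T1", "T2") in edges  # 11 shared genes -> edge
        assert ("T3", "T4") not in edges  # 10 shared genes -> no edge

    def test_time_point_fractions(self):
        res = [result(c, [("T1", ["x"])]) for c in ("a1", "a2", "b1", "b2")]
        net = build_term_network(res, self.meta)
        assert net.nodes[0].time_point_fractions == {"A": 0.5, "B": 0.5}
        assert abs(sum(net.nodes[0].time_point_fractions.values()) - 1.0) < 1e-12

    def test_single_term_no_edges(self):
        net = build_term_network([result("a1", [("T1", ["x", "y"])])], self.meta)
        assert len(net.nodes) == 1 and net.edges == []

    def test_deleting_a_cell_never_adds_an_edge(self):
        shared = [f"s{i}" for i in range(12)]
        res = [
            result("a1", [("T1", shared[:6]), ("T2", shared[:6])]),
            result("a2", [("T1", shared[6:]), ("T2", shared[6:])]),
        ]
        full = build_term_network(res, self.meta)
        reduced = build_term_network(res[:1], self.meta)
        full_edges = {(a, b) for a, b, _ in full.edges}
        reduced_edges = {(a, b) for a, b, _ in reduced.edges}
        assert reduced_edges <= full_edges

    def test_node_counts_both_exported(self, tmp_path):
        res = [result("a1", [("T1", ["x", "y", "z"])]), result("b1", [("T1", ["x"])])]
        net = build_term_network(res, self.meta)
        assert net.nodes[0].n_genes == 3 and net.nodes[0].n_cells == 2
        export_network(net, tmp_path / "n.graphml", tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
        g = nx.read_graphml(tmp_path / "n.graphml")
        assert g.nodes["T1"]["n_genes"] == 3
        assert g.nodes["T1"]["n_cells"] == 2

    def test_graphml_round_trip_counts(self, tmp_path):
        g11 = [f"x{i}" for i in range(11)]
        res = [result("a1", [("T1", g11), ("T2", g11), ("T3", ["q"])])]
        net = build_term_network(res, self.meta)
        export_network(net, tmp_path / "n.graphml")
        g = nx.read_graphml(tmp_path / "n.graphml")
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 1
        assert g.edges["T1", "T2"]["shared_gene_count"] == 11

    def test_empty_network_valid_graphml(self, tmp_path):
        export_network(build_term_network([], self.meta), tmp_path / "n.graphml")
        g = nx.read_graphml(tmp_path / "n.graphml")
        assert g.number_of_nodes() == 0


def test_gmt_round_trip(tmp_path):
    sets = [("T1", "term one", frozenset({"a", "b"})), ("T2", "term two", frozenset({"c"}))]
    write_gmt(sets, tmp_path / "s.gmt")
    assert read_gmt(tmp_path / "s.gmt") == sets
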