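"""Per-cell gene-set enrichment of genes inside significant CNAs, and
construction of the enriched-term network.

For each cell, the genes whose intervals overlap a significant CNA form
the query; each gene set (GO Biological Process style, supplied as GMT)
is scored by the one-sided hypergeometric upper tail against the
annotated-gene universe; Benjamini-Hochberg adjusted p-values above
0.05 are filtered out. Retained terms across cells become nodes of an
undirected network, with an edge between two terms when they share
strictly more than `edge_threshold` genes (default 10, i.e. at least
11), nodes carrying both the gene count and the contributing-cell
count plus the per-time-point fractions used for pie annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .calling import CellCallSet
from .stats import bh_adjust, hypergeometric_tail

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "TermNode",
    "TermNetwork",
    "read_gmt",
    "write_gmt",
    "genes_in_calls",
    "hypergeometric_enrich",
    "bh_adjust",
    "enrich_cell",
    "build_term_network",
    "export_network",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe used for the hypergeometric
    test (all genes of the annotation, since only annotated genes can
    enter a query)."""

    sets: list[tuple[str, str, frozenset[str]]]  # (term_id, term_name, genes)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, _, genes in self.sets:
            if not genes:
                raise ValueError(f"gene set {term_id!r} is empty")

    def restricted_to(self, universe: frozenset[str]) -> "GeneSetCollection":
        """Intersect every set with a new universe, dropping emptied sets."""
        sets = []
        for term_id, name, genes in self.sets:
            g = genes & universe
            if g:
                sets.append((term_id, name, g))
        return GeneSetCollection(sets=sets, universe=universe)


@dataclass
class EnrichmentResult:
    cell_id: str
    rows: list[dict] = field(default_factory=list)
    # each row: term_id, term_name, overlap, p, p_adj, overlap_genes (frozenset)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": self.cell_id,
                    "term_id": r["term_id"],
                    "term_name": r["term_name"],
                    "overlap": r["overlap"],
                    "p": r["p"],
                    "p_adj": r["p_adj"],
                    "overlap_genes": ",".join(sorted(r["overlap_genes"])),
                }
                for r in self.rows
            ],
            columns=["cell_id", "term_id", "term_name", "overlap", "p", "p_adj", "overlap_genes"],
        )


@dataclass
class TermNode:
    term_id: str
    term_name: str
    contributing_cells: frozenset[str]
    gene_set: frozenset[str]
    time_point_fractions: dict[str, float]

    @property
    def n_genes(self) -> int:
        return len(self.gene_set)

    @property
    def n_cells(self) -> int:
        return len(self.contributing_cells)


@dataclass
class TermNetwork:
    nodes: list[TermNode]
    edges: list[tuple[str, str, int]]  # (term_a, term_b, shared_gene_count), a < b


def read_gmt(path) -> list[tuple[str, str, frozenset[str]]]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append((parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for term_id, name, genes in sets:
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def genes_in_calls(
    callset: CellCallSet, annotation: pd.DataFrame, mode: str = "any_overlap"
) -> frozenset[str]:
    """Genes located inside the cell's significant CNAs.

    any_overlap: the gene interval overlaps a call by >= 1 bp;
    contained: the gene interval lies fully inside a call.
    """
    if mode not in ("any_overlap", "contained"):
        raise ValueError(f"unknown mode {mode!r}")
    hits: set[str] = set()
    for c in callset.calls:
        sub = annotation[annotation["chrom"] == c.chrom]
        if mode == "any_overlap":
            sel = (sub["start"] < c.end) & (sub["end"] > c.start)
        else:
            sel = (sub["start"] >= c.start) & (sub["end"] <= c.end)
        hits.update(sub.loc[sel, "gene"].astype(str))
    return frozenset(hits)


def hypergeometric_enrich(
    query: frozenset[str], collection: GeneSetCollection
) -> list[tuple[str, int, float]]:
    """One-sided hypergeometric upper-tail p per term: with a universe of
    N genes, a term of K genes and a query of n genes drawn from the
    universe, p = P[X >= overlap], X ~ Hypergeom(N, K, n)."""
    outside = query - collection.universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were dropped")
        query = query & collection.universe
    if not query:
        warnings.warn("empty query; no enrichment computed")
        return []
    N = len(collection.universe)
    n = len(query)
    out = []
    for term_id, _, genes in collection.sets:
        overlap = len(query & genes)
        out.append((term_id, overlap, hypergeometric_tail(overlap, N, len(genes), n)))
    return out


def enrich_cell(
    callset: CellCallSet,
    annotation: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.05,
    mode: str = "any_overlap",
) -> EnrichmentResult:
    """Full per-cell recipe: genes in calls -> hypergeometric test per
    term -> BH adjustment -> keep terms with adjusted p <= alpha."""
    query = genes_in_calls(callset, annotation, mode=mode)
    if not query:
        return EnrichmentResult(cell_id=callset.cell_id)
    scored = hypergeometric_enrich(query, collection)
    if not scored:
        return EnrichmentResult(cell_id=callset.cell_id)
    names = {tid: name for tid, name, _ in collection.sets}
    sets = {tid: genes for tid, _, genes in collection.sets}
    adj = bh_adjust([p for _, _, p in scored])
    query_in = query & collection.universe
    rows = [
        {
            "term_id": tid,
            "term_name": names[tid],
            "overlap": overlap,
            "p": p,
            "p_adj": float(pa),
            "overlap_genes": query_in & sets[tid],
        }
        for (tid, overlap, p), pa in zip(scored, adj)
        if pa <= alpha and overlap > 0
    ]
    rows.sort(key=lambda r: (r["p_adj"], r["term_id"]))
    return EnrichmentResult(cell_id=callset.cell_id, rows=rows)


def build_term_network(
    results: list[EnrichmentResult],
    metadata: pd.DataFrame,
    edge_threshold: int = 10,
) -> TermNetwork:
    """Aggregate per-cell enrichments into the term network.

    One node per term enriched in at least one cell; its gene set is the
    union of overlap genes across contributing cells, its pie fractions
    the share of contributing cells per blood-draw time point. An edge
    joins two terms iff they share strictly more than edge_threshold
    genes (> 10 by default, i.e. >= 11 shared genes).
    """
    tp_of = dict(zip(metadata["cell_id"].astype(str), metadata["time_point"].astype(str)))
    cells: dict[str, set[str]] = {}
    genes: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for res in results:
        for r in res.rows:
            tid = r["term_id"]
            names[tid] = r["term_name"]
            cells.setdefault(tid, set()).add(res.cell_id)
            genes.setdefault(tid, set()).update(r["overlap_genes"])
    nodes = []
    for tid in sorted(cells):
        tps = [tp_of.get(c, "A") for c in cells[tid]]
        fractions = {tp: tps.count(tp) / len(tps) for tp in sorted(set(tps))}
        nodes.append(
            TermNode(
                term_id=tid,
                term_name=names[tid],
                contributing_cells=frozenset(cells[tid]),
                gene_set=frozenset(genes[tid]),
                time_point_fractions=fractions,
            )
        )
    edges = []
    for a, b in combinations(sorted(cells), 2):
        shared = len(genes[a] & genes[b])
        if shared > edge_threshold:
            edges.append((a, b, shared))
    return TermNetwork(nodes=nodes, edges=edges)


def to_networkx(network: TermNetwork) -> nx.Graph:
    g = nx.Graph()
    for node in network.nodes:
        attrs = {
            "term_name": node.term_name,
            "n_genes": node.n_genes,
            "n_cells": node.n_cells,
        }
        for tp in ("A", "B", "C"):
            attrs[f"frac_{tp}"] = node.time_point_fractions.get(tp, 0.0)
        g.add_node(node.term_id, **attrs)
    for a, b, shared in network.edges:
        g.add_edge(a, b, shared_gene_count=shared)
    return g


def export_network(network: TermNetwork, graphml_path, nodes_tsv=None, edges_tsv=None) -> None:
    """GraphML plus flat node/edge TSVs ready for plotting."""
    nx.write_graphml(to_networkx(network), graphml_path)
    if nodes_tsv is not None:
        pd.DataFrame(
            [
                {
                    "term_id": n.term_id,
                    "term_name": n.term_name,
                    "n_genes": n.n_genes,
                    "n_cells": n.n_cells,
                    "frac_A": n.time_point_fractions.get("A", 0.0),
                    "frac_B": n.time_point_fractions.get("B", 0.0),
                    "frac_C": n.time_point_fractions.get("C", 0.0),
                }
                for n in network.nodes
            ],
            columns=["term_id", "term_name", "n_genes", "n_cells", "frac_A", "frac_B", "frac_C"],
        ).to_csv(nodes_tsv, sep="\t", index=False)
    if edges_tsv is not None:
        pd.DataFrame(
            [{"term_a": a, "term_b": b, "shared_gene_count": s} for a, b, s in network.edges],
            columns=["term_a", "term_b", "shared_gene_count"],
        ).to_csv(edges_tsv, sep="\t", index=False)
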