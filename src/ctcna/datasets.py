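"""Built-in desk-scale fixtures on the toy genome.

The study's focal-region list (23 recurrent amplifications and 19
recurrent deletions from the esophageal-cancer literature) and its GO
Biological Process collection are not redistributable at full scale, so
the package generates deterministic stand-ins on the toy genome: a
region list with the same 23 + 19 composition, a 300-gene annotation,
and a small gene-set collection that includes one physically clustered
"regulation of gene expression"-style term usable for planting
group-specific aberrations in simulations. All fixtures are synthetic
stand-ins produced by code, not curated biology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .genome import toy_genome
from .recurrence import FocalRegion

__all__ = [
    "toy_gene_annotation",
    "toy_gene_sets",
    "toy_focal_regions",
    "REGULATION_TERM_ID",
    "REGULATION_REGION",
]

_GENE_SPACING = 500_000
_GENE_LENGTH = 200_000

# Physically clustered terms: simulations plant recurrent CNAs over these
# intervals so gene-set enrichment has signal. The "regulation" region is
# planted in relapsed cells only (the study's relapse-specific terms); the
# "immune" region is shared by all CTCs (its main network axis).
REGULATION_REGION = ("chr2", 0, 15_000_000)
REGULATION_TERM_ID = "TS0000"
IMMUNE_REGION = ("chr1", 0, 17_000_000)


def toy_gene_annotation() -> pd.DataFrame:
    """300 synthetic genes tiled every 500 kb across the toy genome
    (columns gene, chrom, start, end; 0-based half-open)."""
    rows = []
    k = 0
    for chrom, length in toy_genome().chromosomes:
        n = length // _GENE_SPACING
        for i in range(n):
            k += 1
            start = i * _GENE_SPACING + 100_000
            rows.append({"gene": f"GENE{k:03d}", "chrom": chrom, "start": start, "end": start + _GENE_LENGTH})
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def toy_gene_sets(n_terms: int = 20) -> GeneSetCollection:
    """Synthetic gene-set collection over the toy annotation.

    Term TS0000 ("regulation of gene expression") is the 30 genes
    physically clustered in chr2:0-15 Mb; TS0001/TS0002 (the immune
    pair) are overlapping windows of chr1:0-17 Mb sharing 12 genes, so
    the default network gains an edge under the strict >10 rule; the
    rest are seeded random draws of 25-50 genes.
    """
    ann = toy_gene_annotation()
    universe = frozenset(ann["gene"])

    def genes_in(chrom: str, start: int, end: int) -> frozenset[str]:
        sel = (ann["chrom"] == chrom) & (ann["start"] >= start) & (ann["end"] <= end)
        return frozenset(ann.loc[sel, "gene"])

    reg = genes_in(*REGULATION_REGION)
    rng = np.random.default_rng(20211215)  # fixture constant, not a knob
    genes = np.array(sorted(universe))
    sets: list[tuple[str, str, frozenset[str]]] = [
        (REGULATION_TERM_ID, "regulation of gene expression", reg),
        ("TS0001", "innate immune response", genes_in("chr1", 0, 10_000_000)),
        ("TS0002", "response to cytokine stimulus", genes_in("chr1", 4_000_000, 17_000_000)),
    ]
    for i in range(3, n_terms):
        size = int(rng.integers(25, 51))
        sets.append(
            (f"TS{i:04d}", f"synthetic biological process {i}", frozenset(rng.choice(genes, size=size, replace=False)))
        )
    return GeneSetCollection(sets=sets, universe=universe)


def toy_focal_regions() -> list[FocalRegion]:
    """23 amplification + 19 deletion regions spread over the toy genome,
    with band-style labels and the annotated genes inside each."""
    ann = toy_gene_annotation()
    genome = toy_genome()
    rng = np.random.default_rng(20211216)
    regions: list[FocalRegion] = []
    specs = [("amplification", 23), ("deletion", 19)]
    lengths = {c: L for c, L in genome.chromosomes}
    chrom_names = genome.names
    used: dict[str, int] = {}
    for kind, n in specs:
        for i in range(n):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            width = int(rng.integers(1_000_000, 2_500_000))
            start = int(rng.integers(0, lengths[chrom] - width))
            end = start + width
            used[chrom] = used.get(chrom, 0) + 1
            arm = "p" if start < lengths[chrom] // 2 else "q"
            label = f"{chrom[3:]}{arm}{used[chrom]}{'.1' if kind == 'amplification' else '.2'}_{i}"
            inside = ann[(ann["chrom"] == chrom) & (ann["start"] >= start) & (ann["end"] <= end)]
            regions.append(
                FocalRegion(
                    label=label,
                    chrom=chrom,
                    start=start,
                    end=end,
                    kind=kind,
                    genes=tuple(inside["gene"]),
                )
            )
    return regions
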