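"""Recurrence of focal esophageal-cancer aberrations across CTCs.

Given a curated list of disease-relevant cytogenetic bands (amplified
or deleted focal regions) and the genes inside them, counts how many
CTCs carry at least one significant CNA overlapping each region or
gene, stratified by blood-draw time point (A/B/C) and by clinical
outcome (relapsed / disease-free), and expresses counts as percentages
of the stratum size at one decimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .calling import CellCallSet

__all__ = [
    "FocalRegion",
    "RecurrenceMatrix",
    "load_region_list",
    "write_region_list",
    "region_recurrence",
    "gene_recurrence",
    "stratified_percentages",
]

KINDS = ("amplification", "deletion")


@dataclass(frozen=True)
class FocalRegion:
    """A cytogenetic-band-level region of interest, e.g. an amplification
    at 5q11.2 carrying a known driver gene list."""

    label: str
    chrom: str
    start: int
    end: int
    kind: str
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.label}: end must exceed start")
        if self.kind not in KINDS:
            raise ValueError(f"region {self.label}: unknown kind {self.kind!r}")


@dataclass
class RecurrenceMatrix:
    """Distinct-cell counts per row (region or gene) and stratum.

    counts.loc[row, stratum] is the number of distinct CTCs carrying at
    least one qualifying CNA in the row's interval; totals holds the
    stratum sizes.
    """

    counts: pd.DataFrame  # rows x strata, ints
    totals: dict[str, int]
    row_kind: str  # "region" or "gene"


def load_region_list(path) -> list[FocalRegion]:
    """Read a BED6+ region list: chrom, start, end, label, kind,
    comma-joined genes. Duplicate labels are rejected."""
    regions: list[FocalRegion] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"line {ln}: expected >= 5 tab-separated columns")
            chrom, start, end, label, kind = parts[:5]
            genes = tuple(g for g in parts[5].split(",") if g) if len(parts) > 5 else ()
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"line {ln}: malformed coordinates {start!r}/{end!r}") from exc
            if label in seen:
                raise ValueError(f"duplicate region label {label!r}")
            seen.add(label)
            regions.append(FocalRegion(label, chrom, start_i, end_i, kind, genes))
    if not regions:
        warnings.warn("region list is empty")
    return regions


def write_region_list(regions: list[FocalRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tlabel\tkind\tgenes\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{r.kind}\t{','.join(r.genes)}\n")


def _strata(metadata: pd.DataFrame) -> tuple[dict[str, set[str]], dict[str, int]]:
    """CTC cell-id sets per stratum: the three time points and the two
    outcomes (a cell sits in exactly one of each)."""
    ctc = metadata[metadata["cell_class"] == "CTC"]
    strata: dict[str, set[str]] = {}
    for tp in ("A", "B", "C"):
        strata[f"time_point:{tp}"] = set(ctc.loc[ctc["time_point"] == tp, "cell_id"])
    for out in ("relapsed", "disease_free"):
        strata[f"outcome:{out}"] = set(ctc.loc[ctc["outcome"] == out, "cell_id"])
    totals = {k: len(v) for k, v in strata.items()}
    return strata, totals


def _interval_recurrence(
    callsets: list[CellCallSet],
    rows: list[tuple[str, str, int, int, str | None]],  # (label, chrom, start, end, kind|None)
    metadata: pd.DataFrame,
    match_kind: bool,
    min_overlap: int,
    row_kind: str,
    ploidy: int = 2,
) -> RecurrenceMatrix:
    strata, totals = _strata(metadata)
    ctc_ids = set().union(*strata.values()) if strata else set()
    counts = pd.DataFrame(0, index=[r[0] for r in rows], columns=list(strata), dtype=int)
    for cs in callsets:
        if cs.cell_id not in ctc_ids:
            continue
        cell_strata = [k for k, ids in strata.items() if cs.cell_id in ids]
        for label, chrom, start, end, kind in rows:
            hit = False
            for c in cs.calls:
                if c.chrom != chrom:
                    continue
                overlap = min(c.end, end) - max(c.start, start)
                if overlap < min_overlap:
                    continue
                if match_kind and kind is not None:
                    direction = "amplification" if c.copy_number > ploidy else "deletion"
                    if direction != kind:
                        continue
                hit = True
                break
            if hit:
                for k in cell_strata:
                    counts.loc[label, k] += 1
    return RecurrenceMatrix(counts=counts, totals=totals, row_kind=row_kind)


def region_recurrence(
    callsets: list[CellCallSet],
    regions: list[FocalRegion],
    metadata: pd.DataFrame,
    match_kind: bool = True,
    min_overlap: int = 1,
) -> RecurrenceMatrix:
    """Count, per focal region and stratum, the CTCs with at least one
    call overlapping the region by >= min_overlap bp (and matching the
    region's amplification/deletion kind when match_kind is on)."""
    rows = [(r.label, r.chrom, r.start, r.end, r.kind) for r in regions]
    return _interval_recurrence(callsets, rows, metadata, match_kind, min_overlap, "region")


def gene_recurrence(
    callsets: list[CellCallSet],
    gene_annotation: pd.DataFrame,
    metadata: pd.DataFrame,
    min_overlap: int = 1,
) -> RecurrenceMatrix:
    """Same counting at gene resolution. gene_annotation needs columns
    gene, chrom, start, end; genes with missing coordinates are skipped."""
    rows = []
    for _, g in gene_annotation.iterrows():
        if pd.isna(g["chrom"]) or pd.isna(g["start"]) or pd.isna(g["end"]):
            warnings.warn(f"gene {g['gene']!r} has missing coordinates; skipped")
            continue
        rows.append((str(g["gene"]), str(g["chrom"]), int(g["start"]), int(g["end"]), None))
    return _interval_recurrence(callsets, rows, metadata, match_kind=False, min_overlap=min_overlap, row_kind="gene")


def _round_half_up(x: float, decimals: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0." + "0" * decimals), rounding=ROUND_HALF_UP))


def stratified_percentages(matrix: RecurrenceMatrix) -> pd.DataFrame:
    """Long-format table (row, stratum, count, total, percent) with
    percent = 100 * count / total rounded half-away-from-zero to one
    decimal; strata of size zero report a missing percent."""
    rows = []
    for label in matrix.counts.index:
        for stratum in matrix.counts.columns:
            total = matrix.totals[stratum]
            count = int(matrix.counts.loc[label, stratum])
            percent = _round_half_up(100.0 * count / total) if total > 0 else None
            rows.append(
                {"row": label, "stratum": stratum, "count": count, "total": total, "percent": percent}
            )
    return pd.DataFrame(rows, columns=["row", "stratum", "count", "total", "percent"])


def recurrence_wide(matrix: RecurrenceMatrix) -> pd.DataFrame:
    """Heatmap-ready wide matrix of counts (rows x strata)."""
    return matrix.counts.copy()
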