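"""Readers and writers for the pipeline's plain-text interchange formats.

Counts matrix: TSV with chrom/start/end then one column per cell id.
Metadata: TSV with cell_id, patient_id, time_point, outcome, cell_class,
phenotype. Gene annotation: BED4 (chrom, start, end, gene). All
coordinates 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import BinGrid, GenomeSpec

__all__ = [
    "write_counts",
    "read_counts",
    "write_metadata",
    "read_metadata",
    "read_gene_annotation",
    "write_gene_annotation",
]


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path) -> tuple[BinGrid, pd.DataFrame]:
    """Load a counts TSV and reconstruct the bin grid it was written on
    (chromosome lengths from the last bin end, bin size from the modal
    bin width)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"counts file lacks required column {col!r}")
    chrom_order = list(dict.fromkeys(df["chrom"]))
    genome = GenomeSpec(
        chromosomes=tuple((c, int(df.loc[df["chrom"] == c, "end"].max())) for c in chrom_order)
    )
    widths = (df["end"] - df["start"]).to_numpy()
    bin_size = int(np.bincount(widths).argmax())
    grid = BinGrid(
        genome=genome,
        bin_size=bin_size,
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        gc=df["gc"].to_numpy() if "gc" in df.columns else None,
    )
    cell_cols = [c for c in df.columns if c not in ("chrom", "start", "end", "gc")]
    return grid, df[cell_cols]


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "patient_id", "time_point", "outcome", "cell_class"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks columns {sorted(missing)}")
    return meta


def read_gene_annotation(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"line {ln}: BED4 needs chrom, start, end, gene")
            rows.append({"gene": parts[3], "chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])})
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    if df["gene"].duplicated().any():
        raise ValueError("gene identifiers must be unique")
    return df


def write_gene_annotation(annotation: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgene\n")
        for _, g in annotation.iterrows():
            fh.write(f"{g['chrom']}\t{g['start']}\t{g['end']}\t{g['gene']}\n")
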