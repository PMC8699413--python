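"""Genome coordinates and the bin grid.

Low-pass single-cell WGS is analysed at the resolution of fixed-size
genomic windows ("bins"): reads are counted per bin and every downstream
quantity (copy-number calls, aberrant-bin sets, Jaccard indices) lives on
this grid. The grid tiles each chromosome without gaps or overlaps; the
final bin of a chromosome may be shorter than the nominal bin size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeSpec", "BinGrid", "build_bin_grid", "toy_genome"]


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with lengths in bp."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass
class BinGrid:
    """Fixed-size windows tiling a genome.

    Attributes
    ----------
    genome : GenomeSpec
    bin_size : int
        Nominal window size in bp.
    chrom, start, end : numpy arrays, one entry per bin
        0-based half-open coordinates; bins carry a stable zero-based
        index given by array position, contiguous across chromosomes.
    gc : optional array of per-bin GC fraction in [0, 1].
    """

    genome: GenomeSpec
    bin_size: int
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray | None = None
    _chrom_slices: dict[str, slice] = field(default_factory=dict, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the global bin index covering one chromosome."""
        if not self._chrom_slices:
            for name in self.genome.names:
                idx = np.flatnonzero(self.chrom == name)
                self._chrom_slices[name] = slice(int(idx[0]), int(idx[-1]) + 1)
        return self._chrom_slices[chrom]

    def bins_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of bins whose *midpoint* lies in [start, end)."""
        sl = self.chrom_slice(chrom)
        mid = self.midpoints[sl]
        mask = (mid >= start) & (mid < end)
        return np.arange(sl.start, sl.stop)[mask]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})
        if self.gc is not None:
            df["gc"] = self.gc
        return df


def build_bin_grid(genome: GenomeSpec, bin_size: int) -> BinGrid:
    """Partition a genome into fixed-size windows.

    Each chromosome is tiled left to right; the last window is truncated
    at the chromosome end, so the bin count per chromosome is
    ceil(length / bin_size).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chroms: list[str] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    for name, length in genome.chromosomes:
        s = np.arange(0, length, bin_size, dtype=np.int64)
        e = np.minimum(s + bin_size, length)
        chroms.extend([name] * len(s))
        starts.append(s)
        ends.append(e)
    return BinGrid(
        genome=genome,
        bin_size=bin_size,
        chrom=np.array(chroms, dtype=object),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
    )


def toy_genome() -> GenomeSpec:
    """Desk-scale stand-in genome: six chromosomes, 150 Mb total.

    At the default 50 kb bin size this yields 3,000 bins — large enough
    to exercise segmentation and recurrence, small enough that a full
    cohort runs in seconds.
    """
    return GenomeSpec(
        chromosomes=(
            ("chr1", 40_000_000),
            ("chr2", 35_000_000),
            ("chr3", 25_000_000),
            ("chr4", 20_000_000),
            ("chr5", 18_000_000),
            ("chr6", 12_000_000),
        )
    )


DEFAULT_BIN_SIZE = 50_000
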