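import numpy as np
import pandas as pd
import pytest

from ctcna.calling import CellCallSet, CNACall
from ctcna.genome import BinGrid, GenomeSpec, build_bin_grid


@pytest.fixture(scope="session")
def one_chrom_grid() -> BinGrid:
    """Single 30 Mb chromosome at 20 kb bins -> 1,500 bins."""
    return build_bin_grid(GenomeSpec(chromosomes=(("chr1", 30_000_000),)), 20_000)


@pytest.fixture(scope="session")
def coarse_grid() -> BinGrid:
    """Toy genome at 100 kb bins (1,500 bins) for repeated-run tests."""
    from ctcna.genome import toy_genome

    return build_bin_grid(toy_genome(), 100_000)


def make_callset(cell_id: str, intervals, grid: BinGrid | None = None) -> CellCallSet:
    """Callset from (chrom, start, end, cn) tuples; p-values pass the filter."""
    calls = [
        CNACall(cell_id=cell_id, chrom=c, start=s, end=e, copy_number=cn, p_mw=1e-6, p_ks=1e-6)
        for c, s, e, cn in intervals
    ]
    n = grid.n_bins if grid is not None else 1
    covered = sum(e - s for _, s, e, _ in intervals)
    total = grid.genome.total_length if grid is not None else max(covered, 1)
    return CellCallSet(cell_id=cell_id, calls=calls, aberrant_fraction=covered / total)


def make_metadata(rows) -> pd.DataFrame:
    """Metadata frame from (cell_id, patient, time_point, outcome, cell_class)."""
    return pd.DataFrame(
        rows, columns=["cell_id", "patient_id", "time_point", "outcome", "cell_class"]
    ).assign(phenotype="none")
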