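"""Per-cell copy-number aberration calling from binned counts.

The pipeline re-creates, with documented components, what the study ran
through Control-FREEC on low-pass single-cell BAMs: counts per fixed
window are median-normalized to copy ratios, segmented per chromosome by
penalized least-squares change-point detection on log2 ratios, each
segment is assigned the nearest integer copy number, and a segment is
reported as a CNA only when its bin ratios differ from the cell's own
copy-neutral bins in BOTH a two-sided Mann-Whitney U test and a
two-sample Kolmogorov-Smirnov test at p < 0.05. No multiple-testing
correction is applied to segment p-values — the filter is the raw dual
0.05 rule.

A statsmodels-flavoured surface (`CNAProfileModel.fit()` returning
`CNACallResults` with a `summary()` table) wraps the functional ops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid
from .stats import ks_p, mann_whitney_p

__all__ = [
    "RatioProfile",
    "Segment",
    "CNACall",
    "CellCallSet",
    "normalize_counts",
    "segment_profile",
    "assign_copy_number",
    "score_segment_significance",
    "call_significant_cnas",
    "export_calls",
    "read_calls",
    "CNAProfileModel",
    "CNACallResults",
]

LOG_EPS = 1e-6  # admits zero ratios inside log2
DEFAULT_MIN_BINS = 5
DEFAULT_ALPHA = 0.05
PENALTY_MULTIPLIER = 3.0  # BIC-like: penalty = mult * sigma^2 * log(n)


@dataclass
class RatioProfile:
    """Normalized copy-ratio profile of one cell (ratio 1 ~ diploid)."""

    cell_id: str
    ratios: np.ndarray
    valid_mask: np.ndarray
    grid: BinGrid


@dataclass
class Segment:
    chrom: str
    start_bin: int  # global bin indices, half-open
    end_bin: int
    median_ratio: float
    n_bins: int
    flagged: bool = False  # chromosome too short to segment properly


@dataclass(frozen=True)
class CNACall:
    cell_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    p_mw: float
    p_ks: float


@dataclass
class CellCallSet:
    cell_id: str
    calls: list[CNACall]
    aberrant_fraction: float
    used_fallback_reference: bool = False
    n_segments_tested: int = 0


def normalize_counts(
    counts: np.ndarray,
    grid: BinGrid,
    gc_correct: bool = False,
    cell_id: str = "cell",
    exclude_mask: np.ndarray | None = None,
) -> RatioProfile:
    """Median-normalize bin counts to copy ratios.

    Ratios are counts divided by the median over valid bins, so a
    diploid genome sits at 1. `exclude_mask` marks bins known bad from a
    reference panel; with `gc_correct` and a GC-annotated grid, a
    binned-median GC trend is divided out before scaling.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) != grid.n_bins:
        raise ValueError("counts length does not match grid")
    if not np.any(counts > 0):
        raise ValueError(f"cell {cell_id} has no signal")
    valid = np.ones(grid.n_bins, dtype=bool)
    if exclude_mask is not None:
        valid &= ~np.asarray(exclude_mask, dtype=bool)

    work = counts.copy()
    if gc_correct and grid.gc is not None:
        gc = grid.gc
        extreme = (gc < 0.2) | (gc > 0.8)
        valid &= ~extreme
        # divide out a decile-binned median GC trend
        deciles = np.clip((gc * 10).astype(int), 0, 9)
        trend = np.ones(10)
        overall = np.median(work[valid])
        for d in range(10):
            sel = valid & (deciles == d)
            if sel.sum() >= 10 and overall > 0:
                trend[d] = np.median(work[sel]) / overall
        trend[trend <= 0] = 1.0
        work = work / trend[deciles]

    med = np.median(work[valid])
    if med <= 0:
        raise ValueError(f"cell {cell_id} has no signal")
    return RatioProfile(cell_id=cell_id, ratios=work / med, valid_mask=valid, grid=grid)


def _optimal_partition(y: np.ndarray, penalty: float, min_bins: int) -> list[int]:
    """Change-points of a piecewise-constant least-squares fit.

    Exact optimal partitioning by dynamic programming with a per-segment
    penalty; segment cost is the residual sum of squares, O(1) via
    cumulative sums, O(n^2) overall. Returns interior breakpoints (indices
    into y where a new segment starts).
    """
    n = len(y)
    if n < 2 * min_bins:
        return []
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for j in range(min_bins, n + 1):
        i = np.arange(0, j - min_bins + 1)
        seg_len = j - i
        s = c1[j] - c1[i]
        cost = (c2[j] - c2[i]) - s * s / seg_len
        tot = F[i] + cost + penalty
        k = int(np.argmin(tot))
        F[j] = tot[k]
        prev[j] = i[k]
    bps = []
    j = n
    while j > 0:
        i = prev[j]
        if i > 0:
            bps.append(int(i))
        j = i
    return sorted(bps)


def _auto_penalty(y: np.ndarray) -> float:
    """BIC-like penalty from a difference-based noise estimate (MAD of
    first differences, robust to the change points themselves).

    Homozygous-deletion plateaus have exactly-zero counts and hence zero
    differences; they are excluded so they do not deflate the noise
    estimate and cause oversegmentation elsewhere on the chromosome.
    """
    if len(y) < 3:
        return 1.0
    floor = math.log2(0.1)
    ok = (y[1:] > floor) & (y[:-1] > floor)
    d = np.diff(y)[ok] if ok.sum() >= 10 else np.diff(y)
    sigma = np.median(np.abs(d - np.median(d))) / 0.6745 / math.sqrt(2.0)
    sigma = max(sigma, 1e-3)
    return PENALTY_MULTIPLIER * sigma * sigma * math.log(len(y))


def segment_profile(
    profile: RatioProfile,
    penalty: float | str = "auto",
    min_bins: int = DEFAULT_MIN_BINS,
) -> list[Segment]:
    """Split each chromosome's valid bins into constant-ratio segments.

    Change-point detection runs on log2(ratio + eps). Chromosomes with
    fewer than min_bins valid bins come back as a single flagged segment.
    """
    if min_bins < 2:
        raise ValueError("min_bins must be >= 2")
    grid = profile.grid
    segments: list[Segment] = []
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        idx = np.arange(sl.start, sl.stop)[profile.valid_mask[sl]]
        if len(idx) == 0:
            continue
        ratios = profile.ratios[idx]
        if len(idx) < min_bins:
            segments.append(
                Segment(chrom, int(idx[0]), int(idx[-1]) + 1, float(np.median(ratios)), len(idx), flagged=True)
            )
            continue
        y = np.log2(ratios + LOG_EPS)
        pen = _auto_penalty(y) if penalty == "auto" else float(penalty)
        bps = _optimal_partition(y, pen, min_bins)
        bounds = [0, *bps, len(idx)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_idx = idx[a:b]
            segments.append(
                Segment(
                    chrom=chrom,
                    start_bin=int(seg_idx[0]),
                    end_bin=int(seg_idx[-1]) + 1,
                    median_ratio=float(np.median(ratios[a:b])),
                    n_bins=b - a,
                )
            )
    return segments


def assign_copy_number(segment: Segment, ploidy: int = 2) -> int:
    """Nearest integer copy state: round(median_ratio * ploidy),
    half-away-from-zero, floored at 0."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    x = segment.median_ratio * ploidy
    return max(0, int(math.floor(x + 0.5)))


def score_segment_significance(segment_ratios, neutral_ratios) -> tuple[float, float]:
    """Dual non-parametric significance of a putative CNA segment:
    two-sided Mann-Whitney U and two-sample KS p-values of the segment's
    bin ratios against the cell's copy-neutral bin ratios."""
    segment_ratios = np.asarray(segment_ratios, dtype=float)
    neutral_ratios = np.asarray(neutral_ratios, dtype=float)
    if len(segment_ratios) == 0 or len(neutral_ratios) == 0:
        raise ValueError("both ratio vectors must be non-empty")
    return mann_whitney_p(segment_ratios, neutral_ratios), ks_p(segment_ratios, neutral_ratios)


FALLBACK_REFERENCE_SIZE = 100


def call_significant_cnas(
    profile: RatioProfile,
    segments: list[Segment],
    ploidy: int = 2,
    alpha: float = DEFAULT_ALPHA,
) -> CellCallSet:
    """Emit a CNACall for every segment with copy number != ploidy whose
    ratios pass BOTH tests at p < alpha; merge adjacent passing segments
    of equal copy number.

    The reference sample is the same cell's neutral (CN = ploidy) bins;
    for a wholly aberrant genome a unit-ratio reference of size 100 is
    substituted and the callset is flagged.
    """
    grid = profile.grid
    cns = [assign_copy_number(s, ploidy) for s in segments]
    neutral_idx = [
        np.arange(s.start_bin, s.end_bin)[profile.valid_mask[s.start_bin:s.end_bin]]
        for s, cn in zip(segments, cns)
        if cn == ploidy
    ]
    used_fallback = False
    if neutral_idx:
        neutral = profile.ratios[np.concatenate(neutral_idx)]
    else:
        neutral = np.ones(FALLBACK_REFERENCE_SIZE)
        used_fallback = True

    passing: list[tuple[Segment, int, float, float]] = []
    n_tested = 0
    for s, cn in zip(segments, cns):
        if cn == ploidy:
            continue
        seg_idx = np.arange(s.start_bin, s.end_bin)[profile.valid_mask[s.start_bin:s.end_bin]]
        if len(seg_idx) == 0:
            continue
        n_tested += 1
        p_mw, p_ks = score_segment_significance(profile.ratios[seg_idx], neutral)
        if p_mw < alpha and p_ks < alpha:
            passing.append((s, cn, p_mw, p_ks))

    # merge adjacent passing segments with equal copy number
    passing.sort(key=lambda t: (grid.genome.names.index(t[0].chrom), t[0].start_bin))
    merged: list[tuple[str, int, int, int, float, float]] = []
    for s, cn, p_mw, p_ks in passing:
        if merged:
            mchrom, mstart, mend, mcn, mp_mw, mp_ks = merged[-1]
            if mchrom == s.chrom and mcn == cn and s.start_bin == mend:
                merged[-1] = (mchrom, mstart, s.end_bin, mcn, max(mp_mw, p_mw), max(mp_ks, p_ks))
                continue
        merged.append((s.chrom, s.start_bin, s.end_bin, cn, p_mw, p_ks))

    calls = [
        CNACall(
            cell_id=profile.cell_id,
            chrom=chrom,
            start=int(grid.start[sb]),
            end=int(grid.end[eb - 1]),
            copy_number=cn,
            p_mw=p_mw,
            p_ks=p_ks,
        )
        for chrom, sb, eb, cn, p_mw, p_ks in merged
    ]
    n_valid = int(profile.valid_mask.sum())
    covered = sum(
        int(profile.valid_mask[sb:eb].sum()) for _, sb, eb, _, _, _ in merged
    )
    return CellCallSet(
        cell_id=profile.cell_id,
        calls=calls,
        aberrant_fraction=covered / n_valid if n_valid else 0.0,
        used_fallback_reference=used_fallback,
        n_segments_tested=n_tested,
    )


CALLS_HEADER = "#chrom\tstart\tend\tcell_id\tcopy_number\tp_mw\tp_ks"


def export_calls(callsets: list[CellCallSet], path) -> None:
    """BED7 export: interval, cell id, integer copy number, both p-values."""
    with open(path, "w") as fh:
        fh.write(CALLS_HEADER + "\n")
        for cs in callsets:
            for c in cs.calls:
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{c.cell_id}\t{c.copy_number}"
                    f"\t{c.p_mw:.6g}\t{c.p_ks:.6g}\n"
                )


def read_calls(path) -> list[CellCallSet]:
    by_cell: dict[str, list[CNACall]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, cell_id, cn, p_mw, p_ks = line.split("\t")
            by_cell.setdefault(cell_id, []).append(
                CNACall(cell_id, chrom, int(start), int(end), int(cn), float(p_mw), float(p_ks))
            )
    return [
        CellCallSet(cell_id=cid, calls=sorted(calls, key=lambda c: (c.chrom, c.start)), aberrant_fraction=float("nan"))
        for cid, calls in by_cell.items()
    ]


class CNAProfileModel:
    """Piecewise-constant copy-number model of one cell's binned counts.

    Parameters
    ----------
    counts : array of per-bin read counts
    grid : BinGrid
    cell_id : identifier carried into the calls
    gc_correct : divide out a binned GC trend when the grid carries GC

    `fit` normalizes, segments and applies the dual-test filter,
    returning a :class:`CNACallResults`.
    """

    def __init__(self, counts, grid: BinGrid, cell_id: str = "cell", gc_correct: bool = False):
        self.counts = np.asarray(counts)
        self.grid = grid
        self.cell_id = cell_id
        self.gc_correct = gc_correct

    def fit(
        self,
        penalty: float | str = "auto",
        min_bins: int = DEFAULT_MIN_BINS,
        alpha: float = DEFAULT_ALPHA,
        ploidy: int = 2,
    ) -> "CNACallResults":
        profile = normalize_counts(self.counts, self.grid, self.gc_correct, self.cell_id)
        segments = segment_profile(profile, penalty=penalty, min_bins=min_bins)
        callset = call_significant_cnas(profile, segments, ploidy=ploidy, alpha=alpha)
        return CNACallResults(self, profile, segments, callset, alpha=alpha, ploidy=ploidy)


class CNACallResults:
    """Fitted copy-number profile: segments, significant calls, diagnostics."""

    def __init__(self, model, profile, segments, callset, alpha, ploidy):
        self.model = model
        self.profile: RatioProfile = profile
        self.segments: list[Segment] = segments
        self.callset: CellCallSet = callset
        self.alpha = alpha
        self.ploidy = ploidy

    @property
    def calls(self) -> list[CNACall]:
        return self.callset.calls

    @property
    def aberrant_fraction(self) -> float:
        return self.callset.aberrant_fraction

    def bin_copy_numbers(self) -> pd.DataFrame:
        """Bin-level table (chrom, start, end, ratio, copy_number, in_call)
        mirroring the per-bin copy-number plots of the original pipeline."""
        grid = self.profile.grid
        cn = np.full(grid.n_bins, self.ploidy, dtype=int)
        in_call = np.zeros(grid.n_bins, dtype=bool)
        for c in self.calls:
            idx = grid.bins_overlapping(c.chrom, c.start, c.end)
            cn[idx] = c.copy_number
            in_call[idx] = True
        return pd.DataFrame(
            {
                "chrom": grid.chrom,
                "start": grid.start,
                "end": grid.end,
                "ratio": self.profile.ratios,
                "copy_number": cn,
                "in_call": in_call,
                "valid": self.profile.valid_mask,
            }
        )

    def summary(self) -> pd.DataFrame:
        """One row per significant CNA call."""
        return pd.DataFrame(
            [
                {
                    "cell_id": c.cell_id,
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "copy_number": c.copy_number,
                    "p_mw": c.p_mw,
                    "p_ks": c.p_ks,
                }
                for c in self.calls
            ],
            columns=["cell_id", "chrom", "start", "end", "copy_number", "p_mw", "p_ks"],
        )

    def plot(self, path=None):
        """Scatter of bin ratios colored by call membership, per chromosome."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        grid = self.profile.grid
        fig, ax = plt.subplots(figsize=(10, 3))
        x = np.arange(grid.n_bins)
        tab = self.bin_copy_numbers()
        neutral = ~tab["in_call"].to_numpy()
        ax.scatter(x[neutral], self.profile.ratios[neutral], s=2, c="grey", label="neutral")
        ax.scatter(x[~neutral], self.profile.ratios[~neutral], s=2, c="crimson", label="CNA")
        for chrom in grid.genome.names[1:]:
            ax.axvline(grid.chrom_slice(chrom).start, color="k", lw=0.5)
        ax.set_xlabel("bin index")
        ax.set_ylabel("copy ratio")
        ax.set_title(self.profile.cell_id)
        ax.legend(markerscale=4, fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path)
            plt.close(fig)
        return fig
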