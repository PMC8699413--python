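"""Jaccard-index genomic-imbalance scoring and group comparisons.

Each CTC's imbalance is quantified as the Jaccard index JI(A, B) =
|A n B| / |A u B| between its set A of aberrant bins and the set B of a
reference leukocyte, averaged over five leukocytes analysed with the
same workflow. Because leukocyte call sets are near-empty, JI = 1 reads
as "diploid-like" (complete overlap with a normal diploid genome) and
values near 0 as maximal genomic imbalance; accordingly the empty-vs-
empty case is defined as 1. JI distributions are compared across blood-
draw time points and clinical outcomes with Kruskal-Wallis (more than
two groups) plus pairwise Mann-Whitney U tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .calling import CellCallSet
from .genome import BinGrid
from .stats import kruskal_wallis_p, mann_whitney_p

__all__ = [
    "AberrantBinSet",
    "JIRecord",
    "GroupComparison",
    "aberrant_bin_set",
    "jaccard_index",
    "ji_against_references",
    "ji_table",
    "compare_groups",
    "summarize_distribution",
]


@dataclass
class AberrantBinSet:
    """Bins covered by a cell's significant CNAs, with gain/loss direction."""

    cell_id: str
    bins: frozenset[tuple[int, str]]  # (global bin index, "gain" | "loss")
    n_grid_bins: int

    @property
    def indices(self) -> frozenset[int]:
        return frozenset(b for b, _ in self.bins)


@dataclass
class JIRecord:
    cell_id: str
    per_reference: list[tuple[str, float]]
    summary_ji: float | None


@dataclass
class GroupComparison:
    grouping: str
    group_sizes: dict[str, int]
    medians: dict[str, float]
    kw_p: float | None  # present iff > 2 groups
    pairwise: list[tuple[str, str, float]]

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "group_sizes": self.group_sizes,
            "medians": self.medians,
            "kw_p": self.kw_p,
            "pairwise": [
                {"group_a": a, "group_b": b, "mw_p": p} for a, b, p in self.pairwise
            ],
        }


def aberrant_bin_set(calls: CellCallSet, grid: BinGrid, ploidy: int = 2) -> AberrantBinSet:
    """Collect every bin whose midpoint falls inside a call, tagged gain
    (CN > ploidy) or loss (CN < ploidy)."""
    bins: set[tuple[int, str]] = set()
    for c in calls.calls:
        direction = "gain" if c.copy_number > ploidy else "loss"
        for b in grid.bins_overlapping(c.chrom, c.start, c.end):
            bins.add((int(b), direction))
    return AberrantBinSet(cell_id=calls.cell_id, bins=frozenset(bins), n_grid_bins=grid.n_bins)


def jaccard_index(a: AberrantBinSet, b: AberrantBinSet, direction_mode: str = "status") -> float:
    """|A n B| / |A u B| over aberrant-bin sets.

    status mode compares bare bin indices (an aberration is shared
    regardless of gain/loss direction); signed mode compares
    (bin, direction) pairs. Two empty sets give 1.0: both cells carry an
    identical — fully diploid — aberration content.
    """
    if a.n_grid_bins != b.n_grid_bins:
        raise ValueError("aberrant bin sets come from different grids")
    if direction_mode == "status":
        sa: frozenset = a.indices
        sb: frozenset = b.indices
    elif direction_mode == "signed":
        sa, sb = a.bins, b.bins
    else:
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    union = len(sa | sb)
    if union == 0:
        return 1.0
    return len(sa & sb) / union


def ji_against_references(
    cell: AberrantBinSet,
    refs: list[AberrantBinSet],
    aggregate: str = "mean",
    direction_mode: str = "status",
) -> JIRecord:
    """JI of one CTC against each reference leukocyte, plus the configured
    aggregate (mean by default; "all" keeps per-pair values only)."""
    if not refs:
        raise ValueError("reference leukocyte list must be non-empty")
    per_ref = [(r.cell_id, jaccard_index(cell, r, direction_mode)) for r in refs]
    values = np.array([v for _, v in per_ref])
    if aggregate == "mean":
        summary = float(values.mean())
    elif aggregate == "median":
        summary = float(np.median(values))
    elif aggregate == "all":
        summary = None
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return JIRecord(cell_id=cell.cell_id, per_reference=per_ref, summary_ji=summary)


def ji_table(
    callsets: list[CellCallSet],
    metadata: pd.DataFrame,
    grid: BinGrid,
    aggregate: str = "mean",
    direction_mode: str = "status",
    patient_matched: bool = True,
) -> pd.DataFrame:
    """Score every CTC against its reference leukocytes.

    References default to the cell's patient-matched leukocytes; if a
    patient has none (or patient_matched is False) the cohort leukocyte
    pool is used. Returns one row per CTC with per-reference JIs joined
    with ';', the summary JI and the cell's metadata.
    """
    meta = metadata.set_index("cell_id")
    sets = {cs.cell_id: aberrant_bin_set(cs, grid) for cs in callsets}
    leuk_ids = [cid for cid in sets if meta.loc[cid, "cell_class"] == "leukocyte"]
    by_patient: dict[str, list[str]] = {}
    for cid in leuk_ids:
        by_patient.setdefault(str(meta.loc[cid, "patient_id"]), []).append(cid)

    rows = []
    for cs in callsets:
        if meta.loc[cs.cell_id, "cell_class"] != "CTC":
            continue
        patient = str(meta.loc[cs.cell_id, "patient_id"])
        ref_ids = by_patient.get(patient, []) if patient_matched else leuk_ids
        if not ref_ids:
            ref_ids = leuk_ids
        refs = [sets[r] for r in ref_ids]
        rec = ji_against_references(sets[cs.cell_id], refs, aggregate=aggregate, direction_mode=direction_mode)
        row = {
            "cell_id": cs.cell_id,
            "patient_id": patient,
            "time_point": meta.loc[cs.cell_id, "time_point"],
            "outcome": meta.loc[cs.cell_id, "outcome"],
            "per_reference": ";".join(f"{rid}={v:.6g}" for rid, v in rec.per_reference),
            "summary_ji": rec.summary_ji if rec.summary_ji is not None else np.nan,
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=["cell_id", "patient_id", "time_point", "outcome", "per_reference", "summary_ji"])


def _group_key(grouping: str):
    if grouping == "time_point":
        return ["time_point"]
    if grouping == "outcome":
        return ["outcome"]
    if grouping in ("time_point x outcome", "time_point_x_outcome"):
        return ["time_point", "outcome"]
    raise ValueError(f"unknown grouping {grouping!r}")


def compare_groups(ji: pd.DataFrame, grouping: str, value_col: str = "summary_ji") -> GroupComparison:
    """Kruskal-Wallis (when more than two groups) plus all pairwise
    Mann-Whitney U tests on summary JIs; empty groups are dropped with a
    warning."""
    keys = _group_key(grouping)
    groups: dict[str, np.ndarray] = {}
    for name, sub in ji.groupby(keys, sort=True):
        label = name if isinstance(name, str) else "/".join(map(str, name))
        vals = sub[value_col].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            warnings.warn(f"group {label!r} is empty and was dropped")
            continue
        groups[label] = vals
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    labels = sorted(groups)
    kw = kruskal_wallis_p(list(groups.values())) if len(groups) > 2 else None
    pairwise = [(a, b, mann_whitney_p(groups[a], groups[b])) for a, b in combinations(labels, 2)]
    return GroupComparison(
        grouping=grouping,
        group_sizes={k: len(v) for k, v in groups.items()},
        medians={k: float(np.median(v)) for k, v in groups.items()},
        kw_p=kw,
        pairwise=pairwise,
    )


def summarize_distribution(
    ji: pd.DataFrame,
    grouping: str,
    value_col: str = "summary_ji",
    plot_path=None,
) -> pd.DataFrame:
    """Per-group n / median / IQR table, optionally with a violin plot
    (the study's Fig-style visualization of JI distributions)."""
    keys = _group_key(grouping)
    rows = []
    ordered: list[tuple[str, np.ndarray]] = []
    if len(ji) > 0:
        for name, sub in ji.groupby(keys, sort=True):
            label = name if isinstance(name, str) else "/".join(map(str, name))
            vals = sub[value_col].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"group": label, "n": len(vals), "median": med, "iqr": q3 - q1})
            ordered.append((label, vals))
    table = pd.DataFrame(rows, columns=["group", "n", "median", "iqr"])
    if plot_path is not None and ordered:
        import matplotlib

        matplotlib.use("Agg", force=False)
        # deterministic SVG output so pipeline manifests hash stably
        matplotlib.rcParams["svg.hashsalt"] = "ctcna"
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(ordered), 4))
        ax.violinplot([v for _, v in ordered], showmedians=True)
        ax.set_xticks(range(1, len(ordered) + 1))
        ax.set_xticklabels([k for k, _ in ordered], rotation=30, ha="right")
        ax.set_ylabel("Jaccard index vs leukocytes")
        ax.set_ylim(-0.05, 1.05)
        ax.set_title(f"Genomic imbalance by {grouping}")
        fig.tight_layout()
        save_kwargs = {}
        if str(plot_path).endswith(".svg"):
            save_kwargs["metadata"] = {"Date": None}
        fig.savefig(plot_path, **save_kwargs)
        plt.close(fig)
    return table


def export_comparisons(comparisons: list[GroupComparison], path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in comparisons], fh, indent=2)
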