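"""Synthetic single-cell cohort generator.

The study data (low-pass WGS of DEPArray-sorted CTCs and matched
leukocytes from 11 esophageal-cancer patients) are unpublished, so the
package ships a seeded simulator that emulates them: per-cell binned
read counts with known ground-truth copy-number aberrations, cohort
structure of three blood-draw time points (A before neoadjuvant therapy,
B after it, C after surgery), a relapsed/disease-free outcome per
patient, and five diploid reference leukocytes per patient.

Count model: bin i of a cell with local copy number cn_i draws from a
negative binomial with mean depth_per_bin * cn_i / 2 and variance
mu + dispersion * mu^2; with probability dropout_rate a bin is further
multiplied by a sub-unit factor, emulating WGA locus bias. Relapsed
patients' CTCs carry a larger aberrant genome fraction than
disease-free patients' (default 0.4 vs 0.1), and post-neoadjuvant cells
carry a reduced fraction relative to pre-treatment cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import DEFAULT_BIN_SIZE, BinGrid, GenomeSpec, build_bin_grid, toy_genome

__all__ = [
    "TruthCNA",
    "CellRecord",
    "PatientSpec",
    "CohortSpec",
    "simulate_cell_counts",
    "simulate_cohort",
    "export_truth",
    "read_truth",
    "table1_cohort_spec",
]

TIME_POINTS = ("A", "B", "C")
OUTCOMES = ("disease_free", "relapsed")


@dataclass(frozen=True)
class TruthCNA:
    """A ground-truth aberration: 0-based half-open interval, integer CN != 2."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.copy_number == 2 or self.copy_number < 0:
            raise ValueError("truth copy_number must be a non-negative integer != 2")


@dataclass
class CellRecord:
    """One cell's bin counts plus cohort metadata."""

    cell_id: str
    patient_id: str
    time_point: str
    outcome: str
    cell_class: str  # "CTC" or "leukocyte"
    counts: np.ndarray
    phenotype: str | None = None


@dataclass(frozen=True)
class PatientSpec:
    patient_id: str
    outcome: str
    ctc_counts: dict[str, int]  # time point -> number of CTCs sorted
    aberrant_fraction: float | None = None  # overrides the outcome default


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw one synthetic cohort.

    aberrant_fraction_by_outcome sets the target fraction of the genome
    covered by CNAs for CTCs of each outcome; time_point_multiplier
    rescales it per blood-draw stage (post-neoadjuvant cells are less
    aberrant, mirroring the treatment effect on genomic imbalance).
    biased_regions optionally forces, for one outcome, a CNA over given
    intervals with some probability — used to plant group-specific
    recurrent aberrations.
    """

    patients: tuple[PatientSpec, ...]
    aberrant_fraction_by_outcome: dict[str, float] = field(
        default_factory=lambda: {"relapsed": 0.4, "disease_free": 0.1}
    )
    time_point_multiplier: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "B": 0.6, "C": 1.0}
    )
    n_reference_leukocytes: int = 5
    depth_per_bin: float = 100.0
    dispersion: float = 0.05
    dropout_rate: float = 0.02
    # CNA length model: mixture of arm-scale events (a uniform fraction of a
    # chromosome in [0.3, 1]) and focal events (exponential, mean below).
    arm_event_weight: float = 0.5
    focal_mean_length: float = 4_000_000.0
    copy_state_weights: dict[int, float] = field(
        default_factory=lambda: {0: 0.05, 1: 0.35, 3: 0.40, 4: 0.15, 5: 0.05}
    )
    biased_regions: dict[str, tuple[tuple[str, int, int], ...]] = field(default_factory=dict)
    biased_region_prob: float = 0.9
    # Recurrent WGA artifact regions: locus-specific amplification bias is
    # reproducible across cells prepared with the same chemistry, so a
    # fixed set of low-coverage blocks (drawn once per cohort) is applied
    # to every cell, CTC and leukocyte alike. These shared artifacts are
    # what a diploid leukocyte's CNA calls consist of, and they anchor the
    # Jaccard index: a near-diploid cell shares essentially all its
    # "aberrations" with the reference leukocytes (JI -> 1), while a
    # highly aberrant cell shares only the artifact background (JI -> 0).
    wga_artifact_fraction: float = 0.05
    wga_artifact_block_bins: tuple[int, int] = (5, 20)
    wga_artifact_factor_range: tuple[float, float] = (0.2, 0.5)
    seed: int = 0

    def validate(self) -> None:
        for f in self.aberrant_fraction_by_outcome.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("aberrant fractions must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_reference_leukocytes < 0:
            raise ValueError("n_reference_leukocytes must be >= 0")
        for p in self.patients:
            if p.outcome not in OUTCOMES:
                raise ValueError(f"unknown outcome {p.outcome!r}")
            for tp, n in p.ctc_counts.items():
                if tp not in TIME_POINTS or n < 0:
                    raise ValueError(f"bad CTC count {n} at time point {tp!r}")


def simulate_cell_counts(
    grid: BinGrid,
    truth: list[TruthCNA],
    depth_per_bin: float,
    dispersion: float,
    dropout_rate: float,
    seed: int | np.random.Generator,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one cell's per-bin read counts given its true CNA set.

    A bin's copy number is the truth CN covering its midpoint (2 when no
    event covers it); overlapping truth intervals with conflicting copy
    numbers are rejected. `bias` optionally multiplies the per-bin mean
    (the cohort-wide recurrent WGA artifact map). Identical seed gives
    identical counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cn = np.full(grid.n_bins, 2, dtype=np.int64)
    assigned = np.zeros(grid.n_bins, dtype=bool)
    for ev in truth:
        idx = grid.bins_overlapping(ev.chrom, ev.start, ev.end)
        clash = assigned[idx] & (cn[idx] != ev.copy_number)
        if clash.any():
            raise ValueError(
                f"overlapping truth intervals with conflicting copy numbers at {ev.chrom}"
            )
        cn[idx] = ev.copy_number
        assigned[idx] = True

    mu = depth_per_bin * cn / 2.0
    if bias is not None:
        mu = mu * np.asarray(bias, dtype=float)
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    pos = mu > 0
    if dispersion > 0:
        r = 1.0 / dispersion
        p = r / (r + mu[pos])
        counts[pos] = rng.negative_binomial(r, p)
    else:
        counts[pos] = rng.poisson(mu[pos])
    if dropout_rate > 0:
        hit = rng.random(grid.n_bins) < dropout_rate
        factor = rng.uniform(0.05, 0.5, size=int(hit.sum()))
        counts[hit] = np.floor(counts[hit] * factor).astype(np.int64)
    return counts


def wga_artifact_map(grid: BinGrid, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray | None:
    """Per-bin multiplicative coverage-bias map shared by every cell of a
    cohort: contiguous blocks of depressed amplification efficiency, drawn
    once, covering about wga_artifact_fraction of the bins."""
    if spec.wga_artifact_fraction <= 0:
        return None
    bias = np.ones(grid.n_bins)
    lo, hi = spec.wga_artifact_block_bins
    target = int(spec.wga_artifact_fraction * grid.n_bins)
    covered = 0
    guard = 0
    while covered < target and guard < 10_000:
        guard += 1
        width = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, grid.n_bins - width))
        if np.any(bias[start : start + width] < 1):
            continue
        # keep blocks inside one chromosome
        if grid.chrom[start] != grid.chrom[start + width - 1]:
            continue
        bias[start : start + width] = rng.uniform(*spec.wga_artifact_factor_range)
        covered += width
    return bias


def _draw_truth_cnas(
    grid: BinGrid,
    target_fraction: float,
    spec: CohortSpec,
    rng: np.random.Generator,
    forced: tuple[tuple[str, int, int], ...] = (),
) -> list[TruthCNA]:
    """Sample non-overlapping CNAs until the aberrant bp fraction reaches target."""
    genome = grid.genome
    states = sorted(spec.copy_state_weights)
    weights = np.array([spec.copy_state_weights[s] for s in states], dtype=float)
    weights /= weights.sum()
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    events: list[TruthCNA] = []

    def overlaps(chrom: str, s: int, e: int) -> bool:
        return any(s < e0 and s0 < e for s0, e0 in taken[chrom])

    def add(chrom: str, s: int, e: int, cn: int) -> None:
        taken[chrom].append((s, e))
        events.append(TruthCNA(chrom, s, e, cn))

    for chrom, s, e in forced:
        if not overlaps(chrom, s, e):
            add(chrom, s, e, int(rng.choice(states, p=weights)))

    total = genome.total_length
    aberrant_bp = sum(ev.end - ev.start for ev in events)
    lengths = np.array([L for _, L in genome.chromosomes], dtype=float)
    chrom_p = lengths / lengths.sum()
    attempts = 0
    while aberrant_bp / total < target_fraction and attempts < 500:
        attempts += 1
        ci = int(rng.choice(len(lengths), p=chrom_p))
        chrom, clen = genome.chromosomes[ci]
        if rng.random() < spec.arm_event_weight:
            length = int(clen * rng.uniform(0.3, 1.0))
        else:
            length = int(min(clen, max(grid.bin_size * 2, rng.exponential(spec.focal_mean_length))))
        start = int(rng.integers(0, max(1, clen - length + 1)))
        end = start + length
        if overlaps(chrom, start, end):
            continue
        add(chrom, start, end, int(rng.choice(states, p=weights)))
        aberrant_bp += length
    return sorted(events, key=lambda ev: (genome.names.index(ev.chrom), ev.start))


def simulate_cohort(
    spec: CohortSpec, grid: BinGrid | None = None
) -> tuple[list[CellRecord], list[tuple[str, TruthCNA]]]:
    """Draw the full cohort: every requested CTC plus the per-patient
    reference leukocytes (diploid truth), deterministically under the seed.

    Returns (cells, truth) where truth pairs each CTC id with its events.
    """
    spec.validate()
    if grid is None:
        grid = build_bin_grid(toy_genome(), DEFAULT_BIN_SIZE)
    rng = np.random.default_rng(spec.seed)
    bias = wga_artifact_map(grid, spec, rng)
    phenotypes = np.array(["E", "SM", "mixed"], dtype=object)
    cells: list[CellRecord] = []
    truth_pairs: list[tuple[str, TruthCNA]] = []

    for patient in spec.patients:
        base = (
            patient.aberrant_fraction
            if patient.aberrant_fraction is not None
            else spec.aberrant_fraction_by_outcome[patient.outcome]
        )
        forced = spec.biased_regions.get(patient.outcome, ())
        for tp in TIME_POINTS:
            n_ctc = patient.ctc_counts.get(tp, 0)
            frac = min(1.0, base * spec.time_point_multiplier.get(tp, 1.0))
            for k in range(n_ctc):
                cell_id = f"{patient.patient_id}_{tp}_ctc{k}"
                keep = tuple(r for r in forced if rng.random() < spec.biased_region_prob)
                events = _draw_truth_cnas(grid, frac, spec, rng, forced=keep)
                counts = simulate_cell_counts(
                    grid, events, spec.depth_per_bin, spec.dispersion, spec.dropout_rate, rng, bias=bias
                )
                cells.append(
                    CellRecord(
                        cell_id=cell_id,
                        patient_id=patient.patient_id,
                        time_point=tp,
                        outcome=patient.outcome,
                        cell_class="CTC",
                        counts=counts,
                        phenotype=str(rng.choice(phenotypes)),
                    )
                )
                truth_pairs.extend((cell_id, ev) for ev in events)
        for k in range(spec.n_reference_leukocytes):
            cell_id = f"{patient.patient_id}_leuk{k}"
            counts = simulate_cell_counts(
                grid, [], spec.depth_per_bin, spec.dispersion, spec.dropout_rate, rng, bias=bias
            )
            cells.append(
                CellRecord(
                    cell_id=cell_id,
                    patient_id=patient.patient_id,
                    time_point="A",
                    outcome=patient.outcome,
                    cell_class="leukocyte",
                    counts=counts,
                )
            )
    return cells, truth_pairs


TRUTH_HEADER = "#chrom\tstart\tend\tcell_id\tcopy_number"


def export_truth(truth_pairs: list[tuple[str, TruthCNA]], path) -> None:
    """Write truth CNAs as BED5: 0-based half-open, name = cell id, score = CN."""
    with open(path, "w") as fh:
        fh.write(TRUTH_HEADER + "\n")
        for cell_id, ev in truth_pairs:
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t{cell_id}\t{ev.copy_number}\n")


def read_truth(path) -> list[tuple[str, TruthCNA]]:
    pairs: list[tuple[str, TruthCNA]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, cell_id, cn = line.split("\t")
            pairs.append((cell_id, TruthCNA(chrom, int(start), int(end), int(cn))))
    return pairs


# Per-patient CTC counts arranged so the strata match the study's Table 1:
# time point A = 15 relapsed + 5 disease-free, B = 13 + 14, C = 1 + 9
# (57 CTCs in total over 11 patients).
_TABLE1_LAYOUT: tuple[tuple[str, str, dict[str, int]], ...] = (
    ("R1", "relapsed", {"A": 4, "B": 3, "C": 1}),
    ("R2", "relapsed", {"A": 4, "B": 3, "C": 0}),
    ("R3", "relapsed", {"A": 3, "B": 3, "C": 0}),
    ("R4", "relapsed", {"A": 2, "B": 2, "C": 0}),
    ("R5", "relapsed", {"A": 2, "B": 2, "C": 0}),
    ("D1", "disease_free", {"A": 1, "B": 3, "C": 2}),
    ("D2", "disease_free", {"A": 1, "B": 3, "C": 2}),
    ("D3", "disease_free", {"A": 1, "B": 2, "C": 2}),
    ("D4", "disease_free", {"A": 1, "B": 2, "C": 1}),
    ("D5", "disease_free", {"A": 1, "B": 2, "C": 1}),
    ("D6", "disease_free", {"A": 0, "B": 2, "C": 1}),
)


def table1_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """CohortSpec mirroring the study cohort's published layout.

    11 patients whose per-time-point CTC counts sum to the published
    strata (A: 15 relapsed + 5 disease-free; B: 13 + 14; C: 1 + 9; 57
    CTCs in all), five reference leukocytes per patient. Unless
    overridden, recurrent CNAs are planted over the fixture gene-set
    regions: the immune interval in all CTCs (the shared network axis)
    and the regulation interval in relapsed cells only (the
    relapse-specific terms).
    """
    patients = tuple(PatientSpec(pid, outcome, dict(counts)) for pid, outcome, counts in _TABLE1_LAYOUT)
    if "biased_regions" not in overrides:
        from .datasets import IMMUNE_REGION, REGULATION_REGION

        overrides["biased_regions"] = {
            "relapsed": (IMMUNE_REGION, REGULATION_REGION),
            "disease_free": (IMMUNE_REGION,),
        }
    return CohortSpec(patients=patients, seed=seed, **overrides)


def metadata_frame(cells: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "patient_id": [c.patient_id for c in cells],
            "time_point": [c.time_point for c in cells],
            "outcome": [c.outcome for c in cells],
            "cell_class": [c.cell_class for c in cells],
            "phenotype": [c.phenotype if c.phenotype is not None else "none" for c in cells],
        }
    )


def counts_frame(cells: list[CellRecord], grid: BinGrid) -> pd.DataFrame:
    """Counts matrix in the package's TSV dialect: chrom/start/end then one
    column per cell_id."""
    for c in cells:
        if len(c.counts) != grid.n_bins:
            raise ValueError(f"cell {c.cell_id} count length does not match grid")
    return pd.concat(
        [grid.to_frame()[["chrom", "start", "end"]]]
        + [pd.Series(c.counts, name=c.cell_id) for c in cells],
        axis=1,
    )
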