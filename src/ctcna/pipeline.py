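"""One-command pipeline: simulate -> call -> JI/stats -> recurrence ->
enrichment/network, from a single YAML config, with a hash manifest.

Every stage writes plain-text outputs under the configured directory;
the manifest records sha256 of each file plus the seed and parameters,
so a rerun with the same config is byte-identical. A stage failure
aborts with the stage name and preserves earlier outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import datasets, io
from .calling import CNAProfileModel, export_calls
from .enrichment import (
    GeneSetCollection,
    build_term_network,
    enrich_cell,
    export_network,
    read_gmt,
)
from .genome import DEFAULT_BIN_SIZE, GenomeSpec, build_bin_grid, toy_genome
from .imbalance import compare_groups, export_comparisons, ji_table, summarize_distribution
from .recurrence import (
    gene_recurrence,
    load_region_list,
    region_recurrence,
    stratified_percentages,
)
from .simulate import (
    CohortSpec,
    PatientSpec,
    counts_frame,
    export_truth,
    metadata_frame,
    simulate_cohort,
    table1_cohort_spec,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end run."""

    out_dir: Path
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # mirrors CohortSpec fields
    bin_size: int = DEFAULT_BIN_SIZE
    genome: GenomeSpec | None = None  # None -> toy genome
    calling: dict = field(default_factory=lambda: {"penalty": "auto", "min_bins": 5, "alpha": 0.05})
    imbalance: dict = field(
        default_factory=lambda: {"direction_mode": "status", "aggregate": "mean", "patient_matched": True}
    )
    recurrence: dict = field(default_factory=lambda: {"regions": "builtin", "match_kind": True, "min_overlap": 1})
    enrichment: dict = field(
        default_factory=lambda: {
            "gmt": "builtin",
            "annotation": "builtin",
            "alpha": 0.05,
            "mode": "any_overlap",
            "edge_threshold": 10,
        }
    )

    @classmethod
    def from_yaml(cls, path, out_dir=None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        genome = None
        if "genome" in raw and raw["genome"] not in (None, "toy"):
            genome = GenomeSpec(chromosomes=tuple((c["name"], int(c["length"])) for c in raw["genome"]))
        cfg = cls(
            out_dir=Path(out_dir or raw.get("out_dir", "ctcna_out")),
            seed=int(raw.get("seed", 0)),
            cohort=raw.get("cohort", {}) or {},
            bin_size=int(raw.get("bin_size", DEFAULT_BIN_SIZE)),
            genome=genome,
        )
        for key in ("calling", "imbalance", "recurrence", "enrichment"):
            if key in raw and raw[key]:
                getattr(cfg, key).update(raw[key])
        return cfg

    def cohort_spec(self) -> CohortSpec:
        params = dict(self.cohort)
        layout = params.pop("layout", "table1")
        patients = params.pop("patients", None)
        if patients is not None:
            specs = tuple(
                PatientSpec(
                    patient_id=str(p["patient_id"]),
                    outcome=str(p["outcome"]),
                    ctc_counts={str(k): int(v) for k, v in p.get("ctc_counts", {}).items()},
                    aberrant_fraction=p.get("aberrant_fraction"),
                )
                for p in patients
            )
            return CohortSpec(patients=specs, seed=self.seed, **params)
        if layout != "table1":
            raise ValueError(f"unknown cohort layout {layout!r}")
        return table1_cohort_spec(seed=self.seed, **params)

    def validate(self) -> None:
        self.cohort_spec().validate()
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for key, stage in (("regions", "recurrence"), ("gmt", "enrichment"), ("annotation", "enrichment")):
            cfg = getattr(self, stage)
            val = cfg.get(key, "builtin")
            if val != "builtin" and not Path(val).exists():
                raise PipelineError(stage, f"{key} file not found: {val}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []

    def emit(name: str) -> Path:
        p = out / name
        produced.append(p)
        return p

    # --- simulate -----------------------------------------------------
    try:
        grid = build_bin_grid(config.genome or toy_genome(), config.bin_size)
        spec = config.cohort_spec()
        cells, truth = simulate_cohort(spec, grid)
        meta = metadata_frame(cells)
        io.write_counts(counts_frame(cells, grid), emit("counts.tsv"))
        io.write_metadata(meta, emit("metadata.tsv"))
        export_truth(truth, emit("truth.bed"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    # --- CNA calling --------------------------------------------------
    try:
        cal = config.calling
        callsets = []
        for cell in cells:
            res = CNAProfileModel(cell.counts, grid, cell_id=cell.cell_id).fit(
                penalty=cal.get("penalty", "auto"),
                min_bins=int(cal.get("min_bins", 5)),
                alpha=float(cal.get("alpha", 0.05)),
            )
            callsets.append(res.callset)
        export_calls(callsets, emit("calls.bed"))
        pd.DataFrame(
            {
                "cell_id": [cs.cell_id for cs in callsets],
                "n_calls": [len(cs.calls) for cs in callsets],
                "aberrant_fraction": [round(cs.aberrant_fraction, 6) for cs in callsets],
            }
        ).to_csv(emit("aberrant_fractions.tsv"), sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cna_calling", str(exc)) from exc

    # --- Jaccard imbalance + group statistics -------------------------
    try:
        imb = config.imbalance
        ji = ji_table(
            callsets,
            meta,
            grid,
            aggregate=imb.get("aggregate", "mean"),
            direction_mode=imb.get("direction_mode", "status"),
            patient_matched=bool(imb.get("patient_matched", True)),
        )
        ji.to_csv(emit("ji.tsv"), sep="\t", index=False, float_format="%.6g")
        comparisons = []
        for grouping in ("time_point", "outcome", "time_point x outcome"):
            comparisons.append(compare_groups(ji, grouping))
            slug = grouping.replace(" ", "_")
            summarize_distribution(ji, grouping, plot_path=emit(f"violin_{slug}.svg"))
        export_comparisons(comparisons, emit("comparisons.json"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("imbalance", str(exc)) from exc

    # --- focal recurrence ---------------------------------------------
    try:
        rec = config.recurrence
        regions = (
            datasets.toy_focal_regions()
            if rec.get("regions", "builtin") == "builtin"
            else load_region_list(rec["regions"])
        )
        annotation = (
            datasets.toy_gene_annotation()
            if config.enrichment.get("annotation", "builtin") == "builtin"
            else io.read_gene_annotation(config.enrichment["annotation"])
        )
        rmat = region_recurrence(
            callsets,
            regions,
            meta,
            match_kind=bool(rec.get("match_kind", True)),
            min_overlap=int(rec.get("min_overlap", 1)),
        )
        stratified_percentages(rmat).to_csv(emit("recurrence_regions.tsv"), sep="\t", index=False)
        rmat.counts.to_csv(emit("recurrence_regions_wide.tsv"), sep="\t")
        gmat = gene_recurrence(callsets, annotation, meta, min_overlap=int(rec.get("min_overlap", 1)))
        stratified_percentages(gmat).to_csv(emit("recurrence_genes.tsv"), sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("recurrence", str(exc)) from exc

    # --- enrichment + term network ------------------------------------
    try:
        enr = config.enrichment
        if enr.get("gmt", "builtin") == "builtin":
            collection = datasets.toy_gene_sets()
        else:
            sets = read_gmt(enr["gmt"])
            collection = GeneSetCollection(
                sets=sets, universe=frozenset(annotation["gene"])
            ).restricted_to(frozenset(annotation["gene"]))
        ctc_ids = set(meta.loc[meta["cell_class"] == "CTC", "cell_id"])
        results = [
            enrich_cell(
                cs,
                annotation,
                collection,
                alpha=float(enr.get("alpha", 0.05)),
                mode=enr.get("mode", "any_overlap"),
            )
            for cs in callsets
            if cs.cell_id in ctc_ids
        ]
        frames = [r.to_frame() for r in results if r.rows]
        enrich_df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["cell_id", "term_id", "term_name", "overlap", "p", "p_adj", "overlap_genes"])
        )
        enrich_df.to_csv(emit("enrichment.tsv"), sep="\t", index=False, float_format="%.6g")
        network = build_term_network(results, meta, edge_threshold=int(enr.get("edge_threshold", 10)))
        export_network(
            network,
            emit("network.graphml"),
            nodes_tsv=emit("network_nodes.tsv"),
            edges_tsv=emit("network_edges.tsv"),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("enrichment", str(exc)) from exc

    manifest = {
        "seed": config.seed,
        "parameters": {
            "bin_size": config.bin_size,
            "cohort": config.cohort,
            "calling": config.calling,
            "imbalance": config.imbalance,
            "recurrence": {k: str(v) for k, v in config.recurrence.items()},
            "enrichment": {k: str(v) for k, v in config.enrichment.items()},
        },
        "files": {p.name: _sha256(p) for p in sorted(produced)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
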