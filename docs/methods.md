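# Methods

This note documents the models and procedural choices behind `ctcna`:
what the synthetic cohort emulates, how the CNA caller works, how the
Jaccard imbalance score behaves, and where the open design decisions
were settled. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic cohort

The generator stands in for an unpublished dataset: DEPArray-sorted
single CTCs and matched leukocytes from 11 locally advanced
esophageal-cancer patients, WGA-amplified and sequenced at low pass,
with blood draws at three stages (A before neoadjuvant chemo-radio
therapy, B after it, C after surgery) and a relapsed / disease-free
outcome per patient.

**Count model.** For bin *i* with true local copy number `cn_i`, the
read count is negative binomial with mean `depth_per_bin * cn_i / 2`
and variance `mu + dispersion * mu^2`. Defaults: `depth_per_bin = 100`
(a comfortable low-pass depth at 50 kb bins on the toy genome),
`dispersion = 0.05` (moderate WGA overdispersion: ~24% CV at depth
100), i.i.d. `dropout_rate = 0.02` per bin (count multiplied by a
U(0.05, 0.5) factor). A mean of exactly zero (homozygous deletion)
yields exactly zero counts.

**Recurrent WGA artifacts.** Locus-specific amplification bias in
WGA chemistry is reproducible across cells, not i.i.d. The cohort
therefore draws, once per seed, a set of contiguous low-coverage blocks
(5–20 bins, multiplicative factor U(0.2, 0.5)) covering
`wga_artifact_fraction = 5%` of bins, applied to every cell — CTC and
leukocyte alike. This layer is what gives reference leukocytes a
non-empty, *shared* aberration call set, which in turn is what makes
the Jaccard index informative (section 3). Without it, leukocyte call
sets are empty and every aberrant CTC scores JI ≈ 0 regardless of how
aberrant it is.

**Truth CNAs.** Each CTC receives non-overlapping events sampled until
the target aberrant genome fraction is reached: a mixture of arm-scale
events (30–100% of a chromosome, weight 0.5) and focal events
(exponential, mean 4 Mb), with copy-state weights
{0: .05, 1: .35, 3: .40, 4: .15, 5: .05}. Targets: 0.4 for relapsed
patients' CTCs, 0.1 for disease-free (the published contrast between
the two outcome groups), scaled per time point by {A: 1.0, B: 0.6,
C: 1.0} to encode the observed drop in genomic imbalance after
neoadjuvant therapy; the B multiplier is a stated-world choice (no
published effect size exists) fixed before any acceptance measurement.
Leukocytes carry no truth events. The default cohort layout reproduces
the published strata exactly (57 CTCs: 15+5 at A, 13+14 at B, 1+9 at C
over relapsed/disease-free; 5 leukocytes per patient).

**Recurrent biology.** Real tumor CNAs recur at specific loci. The
default cohort plants, with probability 0.9 per cell, an event over the
fixture "immune" interval (chr1:0–17 Mb, all CTCs) and over the
"regulation" interval (chr2:0–15 Mb, relapsed cells only). This yields
a non-trivial enrichment network with a shared immune axis and
relapse-specific regulation terms, mirroring the structure of the
study's findings. Without recurrence, every hypergeometric test is null
and the network is empty.

**What the generator does not emulate.** GC waves, mappability,
replication timing, subclonal (non-integer) states, chromosome-arm
boundary effects, and sequencing error. A green test therefore
establishes that the pipeline recovers what it models — planted integer
CNAs under NB noise with shared artifacts — not that it would match a
specific real instrument's error profile.

## 2. CNA calling

- **Normalization**: ratios = counts / median(counts over valid bins).
  This pins the *majority* state to ratio 1, so it assumes most of the
  genome is copy-neutral; see limitations. Optional GC correction
  divides out a decile-binned median trend when the grid carries GC.
- **Segmentation**: exact optimal partitioning (dynamic programming,
  O(n²) per chromosome) minimizing within-segment sum of squares on
  log2(ratio + 1e-6), per-segment penalty `3 σ² log n` with σ estimated
  from the MAD of first differences. Zero-count plateaus (homozygous
  deletions give log2 ≈ −20 exactly, with zero variance) are excluded
  from the σ estimate so they do not deflate it and oversegment the
  rest of the chromosome. Minimum segment length 5 bins; chromosomes
  shorter than that come back as one flagged segment.
- **Copy number**: CN = max(0, round(ploidy · median ratio)), half away
  from zero, ploidy fixed at 2.
- **Significance**: each non-neutral segment's bin ratios are compared
  with the same cell's CN = 2 bins by a two-sided Mann–Whitney U test
  (exact tie-aware enumeration when both sides ≤ 8, tie-corrected
  normal approximation otherwise) and a two-sample KS test; a call
  requires p < 0.05 in **both**, with no multiple-testing correction
  (the number of segments tested is recorded on the callset). A wholly
  aberrant genome falls back to a unit-ratio reference of 100 bins and
  flags the callset. Adjacent passing segments with equal CN merge.

## 3. Jaccard genomic imbalance

JI(A, B) = |A ∩ B| / |A ∪ B| over aberrant-*bin* sets (bin resolution
matches calling resolution). Defaults: direction-agnostic ("status")
sets; mean over the five patient-matched leukocytes (cohort pool when a
patient has none); signed mode and per-pair ("all") outputs available.
Two empty sets give JI = 1: identical, fully diploid content — the
interpretation under which JI = 1 means complete overlap with a normal
diploid genome.

Behaviour under the artifact model: with a shared artifact set of s
bins and a CTC aberrant over fraction f of N bins,
JI ≈ s / (fN + s) — equal to 1 at f = 0 and decreasing smoothly in f.
This is what the monotonicity test (Spearman ρ < −0.9 across cells
spanning f = 0–0.6) verifies, and why relapsed cells (f = 0.4) score
systematically below disease-free cells (f = 0.1).

Group comparison: Kruskal–Wallis when more than two groups, pairwise
two-sided Mann–Whitney U for every pair, group medians and IQRs
reported, violin plots exported as SVG (deterministic metadata so
pipeline manifests hash stably).

## 4. Recurrence and enrichment

- Recurrence counts a cell at most once per (row, stratum); overlap
  rule ≥ 1 bp (configurable minimum), direction matching on by default
  (amplification ⇔ CN > 2). Percentages are 100·k/n rounded half away
  from zero to one decimal; zero-size strata report an absent, not 0,
  percentage.
- Enrichment: per-cell query = genes overlapping any significant CNA
  (`any_overlap` default; `contained` honors strict containment);
  one-sided hypergeometric upper tail with the *annotation* as universe
  (only annotated genes can enter a query); Benjamini–Hochberg
  adjustment; retained at adjusted p ≤ 0.05.
- Network: node per term enriched in ≥ 1 cell; node gene set = union of
  overlap genes across contributing cells; edge iff strictly more than
  `edge_threshold = 10` shared genes (≥ 11). Nodes carry both n_genes
  and n_cells — sources disagree on which drives node size, so both are
  exported and the plot key is a config choice; time-point fractions
  count cells (a flag can collapse to patient-time point samples).

## 5. Numerical and design notes

- All randomness flows from one `numpy` Generator seeded explicitly; no
  global state. Same config + seed ⇒ byte-identical outputs (the
  pipeline manifest records sha256 per file).
- ε = 1e−6 inside log2 admits zero ratios; copy-number rounding ties go
  away from zero (1.25 ratio → CN 3).
- Exact MW enumeration is permutation-based and therefore valid under
  ties; scipy's exact method (tie-free only) is used as a cross-check
  in the tests, never as the implementation oracle for tied data.
- Coordinates are 0-based half-open everywhere (internally and in BED
  exports); bin → bp conversion uses bin boundaries.
- The toy genome (6 chromosomes, 150 Mb, 3,000 bins at 50 kb) keeps a
  full cohort run under ~10 s; any genome can be supplied via
  `GenomeSpec`/YAML. Repeated-run tests use 100 kb bins (1,500 bins)
  purely for runtime.

## 6. Known limitations

- Median normalization mis-centers cells whose aberrant fraction
  approaches half the genome (a 500-bin CN 4 event on a 1,500-bin
  genome shifts the median enough to round CN 4 down to 3). Real
  pipelines re-fit ploidy; here ploidy is fixed at 2 by design.
- Raw dual-test filtering at p < 0.05 per segment, without correction,
  follows the original procedure; on thousands of segments it admits
  false positives by construction.
- The fixture region list and gene-set collection are deterministic
  synthetic stand-ins on the toy genome, not curated esophageal-cancer
  biology; user-supplied hg19-scale lists load through the same
  interfaces.
- Segment p-values treat bins as independent; autocorrelation from GC
  or mappability waves in real data would inflate significance.
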