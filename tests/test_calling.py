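import numpy as np
import pytest

from ctcna.calling import (
    LOG_EPS,
    CNAProfileModel,
    RatioProfile,
    Segment,
    assign_copy_number,
    call_significant_cnas,
    export_calls,
    normalize_counts,
    read_calls,
    score_segment_significance,
    segment_profile,
)
from ctcna.genome import GenomeSpec, build_bin_grid
from ctcna.simulate import TruthCNA, simulate_cell_counts
from ctcna.stats import ks_p, mann_whitney_p


def grid_of(n_bins, bin_size=10_000, name="chr1"):
    return build_bin_grid(GenomeSpec(chromosomes=((name, n_bins * bin_size),)), bin_size)


class TestNormalize:
    def test_constant_counts_give_unit_ratios(self):
        g = grid_of(100)
        prof = normalize_counts(np.full(100, 100), g)
        np.testing.assert_allclose(prof.ratios, 1.0)

    def test_doubled_region_gives_ratio_two(self):
        g = grid_of(100)
        counts = np.full(100, 100)
        counts[80:] = 200
        prof = normalize_counts(counts, g)
        np.testing.assert_allclose(prof.ratios[:80], 1.0)
        np.testing.assert_allclose(prof.ratios[80:], 2.0)

    def test_all_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            normalize_counts(np.zeros(100), grid_of(100))

    def test_median_near_one_after_normalization(self):
        rng = np.random.default_rng(0)
        g = grid_of(1000)
        prof = normalize_counts(rng.poisson(100, 1000), g)
        assert 0.95 <= np.median(prof.ratios[prof.valid_mask]) <= 1.05


def _exhaustive_single_cp(y, min_bins):
    """Oracle: least-squares scan over every admissible single change point."""
    n = len(y)
    best_cost, best_k = np.inf, None
    for k in range(min_bins, n - min_bins + 1):
        cost = np.var(y[:k]) * k + np.var(y[k:]) * (n - k)
        if cost < best_cost:
            best_cost, best_k = cost, k
    return best_k


class TestSegmentation:
    def test_single_step_recovered_within_three_bins(self):
        rng = np.random.default_rng(42)
        ratios = np.concatenate([np.ones(1000), np.full(500, 2.0)]) + rng.normal(0, 0.05, 1500)
        g = grid_of(1500)
        prof = RatioProfile("c", ratios, np.ones(1500, bool), g)
        segs = segment_profile(prof, penalty="auto", min_bins=5)
        assert len(segs) == 2
        assert abs(segs[0].end_bin - 1000) <= 3
        oracle = _exhaustive_single_cp(np.log2(ratios + LOG_EPS), 5)
        assert abs(segs[0].end_bin - oracle) <= 3

    def test_constant_profile_one_segment_per_chromosome(self):
        g = build_bin_grid(GenomeSpec(chromosomes=(("chr1", 2_000_000), ("chr2", 1_000_000))), 10_000)
        prof = RatioProfile("c", np.ones(g.n_bins), np.ones(g.n_bins, bool), g)
        segs = segment_profile(prof)
        assert [s.chrom for s in segs] == ["chr1", "chr2"]

    def test_two_sided_step_gives_three_segments(self):
        """1.0 -> 0.5 -> 1.0 on 300 bins; boundaries agree with an
        exhaustive two-change-point least-squares scan."""
        rng = np.random.default_rng(7)
        ratios = np.concatenate([np.ones(120), np.full(60, 0.5), np.ones(120)]) + rng.normal(0, 0.05, 300)
        y = np.log2(ratios + LOG_EPS)
        # oracle: all (k1, k2) pairs with min segment length 5
        best, pair = np.inf, None
        for k1 in range(5, 291):
            for k2 in range(k1 + 5, 296):
                cost = (
                    np.var(y[:k1]) * k1 + np.var(y[k1:k2]) * (k2 - k1) + np.var(y[k2:]) * (300 - k2)
                )
                if cost < best:
                    best, pair = cost, (k1, k2)
        g = grid_of(300)
        prof = RatioProfile("c", ratios, np.ones(300, bool), g)
        segs = segment_profile(prof, min_bins=5)
        assert len(segs) == 3
        assert abs(segs[0].end_bin - pair[0]) <= 3
        assert abs(segs[1].end_bin - pair[1]) <= 3

    def test_short_chromosome_single_flagged_segment(self):
        g = build_bin_grid(GenomeSpec(chromosomes=(("chr1", 30_000),)), 10_000)
        prof = RatioProfile("c", np.ones(3), np.ones(3, bool), g)
        segs = segment_profile(prof, min_bins=5)
        assert len(segs) == 1 and segs[0].flagged

    def test_segments_tile_valid_bins(self):
        rng = np.random.default_rng(3)
        g = grid_of(400)
        prof = RatioProfile("c", rng.normal(1, 0.2, 400).clip(0), np.ones(400, bool), g)
        segs = segment_profile(prof)
        bounds = sorted((s.start_bin, s.end_bin) for s in segs)
        assert bounds[0][0] == 0 and bounds[-1][1] == 400
        for (a, b), (c, d) in zip(bounds[:-1], bounds[1:]):
            assert b == c
        assert all(s.n_bins >= 5 for s in segs)


@pytest.mark.parametrize(
    "median_ratio, expected",
    [(1.52, 3), (0.02, 0), (1.25, 3), (1.0, 2), (0.5, 1)],  # 1.25*2=2.5 rounds away from zero
)
def test_assign_copy_number(median_ratio, expected):
    seg = Segment("chr1", 0, 10, median_ratio, 10)
    assert assign_copy_number(seg, ploidy=2) == expected


class TestSignificance:
    def test_mw_example_exact(self):
        p_mw, _ = score_segment_significance([1, 2, 3], [4, 5, 6])
        assert p_mw == pytest.approx(0.1)

    def test_ks_disjoint_supports(self):
        from scipy.stats import ks_2samp

        assert ks_2samp([1, 2], [3, 4]).statistic == 1.0
        _, p_ks = score_segment_significance([1, 2], [3, 4])
        assert p_ks == pytest.approx(ks_p([1, 2], [3, 4]))

    def test_identical_samples_not_significant(self):
        p_mw, p_ks = score_segment_significance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p_mw == pytest.approx(1.0)
        assert p_ks > 0.9


class TestCalling:
    def test_failing_ks_blocks_call(self, one_chrom_grid):
        """A segment must pass BOTH tests; a tiny aberrant segment against
        overwhelming neutral noise fails at least one and is dropped."""
        rng = np.random.default_rng(1)
        n = one_chrom_grid.n_bins
        ratios = rng.normal(1, 0.3, n).clip(0.01)
        prof = RatioProfile("c", ratios, np.ones(n, bool), one_chrom_grid)
        # hand-made segmentation: one small "CN 3" segment of noise bins
        segs = [
            Segment("chr1", 0, 6, 1.48, 6),
            Segment("chr1", 6, n, float(np.median(ratios[6:])), n - 6),
        ]
        cs = call_significant_cnas(prof, segs)
        for call in cs.calls:
            assert call.p_mw < 0.05 and call.p_ks < 0.05

    def test_diploid_cells_rarely_called(self, coarse_grid):
        """Caller specificity under its own null: a diploid cell with
        moderate noise yields zero calls in >= 95% of 100 seeded runs."""
        clean = 0
        for seed in range(100):
            counts = simulate_cell_counts(coarse_grid, [], 100, 0.05, 0.0, seed=seed)
            res = CNAProfileModel(counts, coarse_grid, cell_id=f"d{seed}").fit()
            clean += len(res.calls) == 0
        assert clean >= 95

    def test_single_event_recovery(self):
        """One 500-bin CN=4 event at depth 100, dispersion 0.05: exactly one
        call, breakpoints within +/- 3 bins, CN 4. The event covers 1/6 of
        the genome; median normalization assumes the neutral state is the
        majority, so the genome must dwarf the event."""
        g = grid_of(3000, bin_size=20_000)
        ev = TruthCNA("chr1", 10_000_000, 20_000_000, 4)  # bins 500..999
        counts = simulate_cell_counts(g, [ev], 100, 0.05, 0.0, seed=9)
        res = CNAProfileModel(counts, g, cell_id="c").fit()
        assert len(res.calls) == 1
        call = res.calls[0]
        assert call.copy_number == 4
        assert abs(call.start - ev.start) <= 3 * 20_000
        assert abs(call.end - ev.end) <= 3 * 20_000

    def test_filter_monotone_in_alpha(self, one_chrom_grid):
        rng = np.random.default_rng(5)
        events = [TruthCNA("chr1", 2_000_000, 6_000_000, 3), TruthCNA("chr1", 14_000_000, 18_000_000, 1)]
        counts = simulate_cell_counts(one_chrom_grid, events, 100, 0.3, 0.05, seed=12)
        prof = normalize_counts(counts, one_chrom_grid, cell_id="c")
        segs = segment_profile(prof)
        n_strict = len(call_significant_cnas(prof, segs, alpha=0.01).calls)
        n_mid = len(call_significant_cnas(prof, segs, alpha=0.05).calls)
        n_loose = len(call_significant_cnas(prof, segs, alpha=0.5).calls)
        assert n_strict <= n_mid <= n_loose

    def test_wholly_aberrant_genome_uses_fallback_reference(self, one_chrom_grid):
        counts = simulate_cell_counts(
            one_chrom_grid, [TruthCNA("chr1", 0, 30_000_000, 4)], 100, 0.02, 0.0, seed=2
        )
        # median-normalization puts CN4 at ratio 1, so the fallback only
        # triggers when ratios are supplied on an absolute scale
        n = one_chrom_grid.n_bins
        prof = RatioProfile("c", np.full(n, 2.0) + np.random.default_rng(0).normal(0, 0.02, n), np.ones(n, bool), one_chrom_grid)
        segs = segment_profile(prof)
        cs = call_significant_cnas(prof, segs)
        assert cs.used_fallback_reference
        assert len(cs.calls) >= 1 and all(c.copy_number == 4 for c in cs.calls)


class TestExport:
    def test_round_trip_and_column_count(self, tmp_path, one_chrom_grid):
        counts = simulate_cell_counts(
            one_chrom_grid, [TruthCNA("chr1", 10_000_000, 20_000_000, 4)], 100, 0.05, 0.0, seed=9
        )
        res = CNAProfileModel(counts, one_chrom_grid, cell_id="c1").fit()
        p = tmp_path / "calls.bed"
        export_calls([res.callset], p)
        lines = [ln for ln in p.read_text().splitlines() if not ln.startswith("#")]
        assert len(lines) == len(res.calls)
        assert all(len(ln.split("\t")) == 7 for ln in lines)
        back = read_calls(p)
        assert len(back) == 1
        assert [(c.chrom, c.start, c.end, c.copy_number) for c in back[0].calls] == [
            (c.chrom, c.start, c.end, c.copy_number) for c in res.calls
        ]

    def test_empty_callset_valid_file(self, tmp_path):
        from ctcna.calling import CellCallSet

        p = tmp_path / "calls.bed"
        export_calls([CellCallSet("c", [], 0.0)], p)
        assert read_calls(p) == []


def test_model_summary_shape(one_chrom_grid):
    counts = simulate_cell_counts(
        one_chrom_grid, [TruthCNA("chr1", 10_000_000, 20_000_000, 4)], 100, 0.05, 0.0, seed=9
    )
    res = CNAProfileModel(counts, one_chrom_grid, cell_id="c1").fit()
    tab = res.summary()
    assert list(tab.columns) == ["cell_id", "chrom", "start", "end", "copy_number", "p_mw", "p_ks"]
    assert (tab["p_mw"] < 0.05).all() and (tab["p_ks"] < 0.05).all()
    bins = res.bin_copy_numbers()
    assert len(bins) == one_chrom_grid.n_bins
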