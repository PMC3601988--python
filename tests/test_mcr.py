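"""Multicopy-region detection: GC correction, CN, chaining, overlaps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poolscan.io_windows import AlleleCount, DepthSpectrum, GenomeWindow
from poolscan.mcr import (
    DepthBin,
    MCRSegment,
    chain_mcrs,
    copy_number,
    gc_correct,
    gene_overlap,
    mcr_window_overlap,
)
from poolscan.simulate import sim_depth_track


def _bins(cns, chrom="chr1", start0=0, depth_per_cn=3.5, gc=0.45):
    return [
        DepthBin(chrom, start0 + i * 1000, raw_depth=depth_per_cn * cn,
                 gc_fraction=gc, corrected_depth=depth_per_cn * cn, cn=cn)
        for i, cn in enumerate(cns)
    ]


class TestGcCorrect:
    def test_flat_depth_unchanged(self):
        bins = [
            DepthBin("c", i * 1000, 7.0, 0.30 + 0.001 * (i % 300))
            for i in range(600)
        ]
        out = gc_correct(bins)
        assert all(b.corrected_depth == pytest.approx(7.0) for b in out)

    def test_biased_interval_rescaled(self):
        # baseline: depth 7 everywhere except GC ~0.50 where it is 14
        base = [DepthBin("c", i * 1000, 7.0, 0.40) for i in range(100)]
        base += [DepthBin("c", (100 + i) * 1000, 14.0, 0.50) for i in range(100)]
        bins = [DepthBin("c", 0, 30.0, 0.50)]
        out = gc_correct(bins, baseline_bins=base)
        # factor at 0.50 = overall(10.5) / 14 = 0.75 -> 22.5
        assert out[0].corrected_depth == pytest.approx(30.0 * 10.5 / 14.0)

    def test_empty_interval_borrows_nearest(self):
        base = [DepthBin("c", i * 1000, 7.0, 0.40) for i in range(100)]
        bins = [DepthBin("c", 0, 10.0, 0.90)]
        out = gc_correct(bins, baseline_bins=base)
        assert out[0].corrected_depth == pytest.approx(10.0)

    def test_no_baseline_raises(self):
        with pytest.raises(ValueError):
            gc_correct([DepthBin("c", 0, 5.0, 0.4, masked_fraction=0.9)])

    def test_preserves_baseline_mean(self):
        rng = np.random.default_rng(5)
        gc = rng.uniform(0.3, 0.6, 2000)
        depth = rng.poisson(7000, 2000) / 1000 * (1 + (gc - 0.45))
        bins = [
            DepthBin("c", i * 1000, float(depth[i]), float(gc[i]))
            for i in range(2000)
        ]
        out = gc_correct(bins)
        assert np.mean([b.corrected_depth for b in out]) == pytest.approx(
            np.mean(depth), rel=0.01
        )


class TestCopyNumber:
    @pytest.mark.parametrize(
        "ratio,cn", [(1.0, 2), (1.5, 3), (1.24, 2), (1.25, 3), (2.0, 4)]
    )
    def test_half_up_rounding(self, ratio, cn):
        b = DepthBin("c", 0, 0.0, 0.4, corrected_depth=7.0 * ratio)
        assert copy_number([b], 7.0)[0].cn == cn

    def test_domain(self):
        with pytest.raises(ValueError):
            copy_number([], 0.0)


class TestChainMcrs:
    def test_contiguous_run(self):
        segs = chain_mcrs(_bins([3, 3, 3, 3]))
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 4000)
        assert segs[0].mean_cn == 3.0 and segs[0].n_bins == 4

    def test_single_gap_bridged(self):
        segs = chain_mcrs(_bins([3, 3, 2, 3, 3]))
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 5000)
        assert segs[0].n_bins == 4  # gap bin not counted

    def test_double_gap_splits_below_min_length(self):
        assert chain_mcrs(_bins([3, 3, 2, 2, 3, 3])) == []

    def test_short_run_discarded(self):
        assert chain_mcrs(_bins([3, 3, 3])) == []

    def test_sub_threshold_bins_ignored(self):
        assert chain_mcrs(_bins([2, 2, 2, 2, 2, 2])) == []

    @given(st.lists(st.integers(0, 6), min_size=1, max_size=80))
    def test_output_always_satisfies_constraints(self, cns):
        bins = _bins(cns)
        segs = chain_mcrs(bins)
        by_start = {b.start: b for b in bins}
        for seg in segs:
            assert seg.length >= 4000
            first = by_start[seg.start]
            last = by_start[seg.end - 1000]
            assert first.cn >= 3 and last.cn >= 3
            # no two consecutive sub-threshold/missing bins inside
            gap_run = 0
            for pos in range(seg.start, seg.end, 1000):
                b = by_start.get(pos)
                if b is None or b.cn < 3:
                    gap_run += 1
                    assert gap_run <= 1
                else:
                    gap_run = 0
        # idempotence: chaining the qualifying bins again changes nothing
        again = chain_mcrs(bins)
        assert [(s.start, s.end) for s in again] == [
            (s.start, s.end) for s in segs
        ]


class TestPlantedSegmentRecovery:
    def test_recovery_with_one_bin_boundary_error(self):
        planted = [(20_000, 30_000, 4), (60_000, 66_000, 3)]
        bins, truth = sim_depth_track(
            100_000, diploid_depth=7.0, planted_segments=planted, seed=11
        )
        corrected = gc_correct(bins)
        with_cn = copy_number(corrected, 7.0)
        segs = chain_mcrs(with_cn)
        assert len(segs) == len(planted)
        for (s, e, cn), seg in zip(planted, segs):
            assert abs(seg.start - s) <= 1000 and abs(seg.end - e) <= 1000
            assert round(seg.mean_cn) == cn

    def test_deterministic_under_seed(self):
        a, _ = sim_depth_track(50_000, 7.0, [(10_000, 20_000, 5)], seed=3)
        b, _ = sim_depth_track(50_000, 7.0, [(10_000, 20_000, 5)], seed=3)
        assert [x.raw_depth for x in a] == [x.raw_depth for x in b]

    def test_overlapping_planted_rejected(self):
        with pytest.raises(ValueError):
            sim_depth_track(50_000, 7.0, [(0, 10_000, 3), (5_000, 15_000, 4)])


class TestGeneOverlap:
    SEGS = [MCRSegment("chr1", 10_000, 20_000, 4.0, 10)]

    def test_gene_inside_is_full(self):
        out = gene_overlap(self.SEGS, [("chr1", 12_000, 18_000, "gA")])
        assert out["gA"][0] == "full"

    def test_sixty_percent_is_partial(self):
        out = gene_overlap(self.SEGS, [("chr1", 16_000, 26_000, "gB")])
        assert out["gB"] == ("partial", pytest.approx(0.4)) or out["gB"][0] in (
            "none",
        )
        # 60% covered version
        out = gene_overlap(self.SEGS, [("chr1", 14_000, 24_000, "gC")])
        assert out["gC"][0] == "partial" and out["gC"][1] == pytest.approx(0.6)

    def test_exactly_half_is_none(self):
        out = gene_overlap(self.SEGS, [("chr1", 15_000, 25_000, "gD")])
        assert out["gD"][0] == "none" and out["gD"][1] == pytest.approx(0.5)

    def test_merged_coverage_across_segments(self):
        segs = [
            MCRSegment("chr1", 0, 5_000, 3.0, 5),
            MCRSegment("chr1", 4_000, 10_000, 3.0, 6),
        ]
        out = gene_overlap(segs, [("chr1", 0, 10_000, "gE")])
        assert out["gE"][0] == "full"

    def test_zero_length_gene_rejected(self):
        with pytest.raises(ValueError):
            gene_overlap(self.SEGS, [("chr1", 5, 5, "gF")])


class TestMcrWindowOverlap:
    def _window(self, sites):
        spec = DepthSpectrum()
        for s in sites:
            spec.add(s.depth)
        return GenomeWindow("chr1", 0, 200_000, spec,
                            S=sum(1 for s in sites if s.segregating),
                            sites=sites)

    def test_no_segments_all_without_stratum(self):
        sites = [
            AlleleCount("chr1", i, "A", 8, 2, "G", 30, 30, segregating=True)
            for i in range(100)
        ]
        splits, summary = mcr_window_overlap([], [self._window(sites)], 18)
        assert splits[0].stratum == "without_mcr"
        assert np.isnan(summary["inside_mcr"])

    def test_snps_only_inside_gives_zero_outside(self):
        inside = [
            AlleleCount("chr1", i, "A", 8, 2, "G", 30, 30, segregating=True)
            for i in range(1000, 1050)
        ]
        outside = [
            AlleleCount("chr1", i, "A", 8, 0, None, 30, 0, segregating=False)
            for i in range(50_000, 50_100)
        ]
        w = self._window(inside + outside)
        seg = MCRSegment("chr1", 0, 5_000, 3.0, 5)
        splits, _ = mcr_window_overlap([seg], [w], 18)
        assert splits[0].theta_outside == 0.0
        assert splits[0].theta_inside > 0

    def test_stratum_means_match_hand_computation(self):
        from poolscan.diversity import theta_w_pool

        inside = [
            AlleleCount("chr1", i, "A", 6, 2, "G", 30, 30, segregating=True)
            for i in range(1000, 1020)
        ] + [
            AlleleCount("chr1", i, "A", 8, 0, None, 30, 0, segregating=False)
            for i in range(2000, 2080)
        ]
        outside = [
            AlleleCount("chr1", i, "A", 6, 2, "G", 30, 30, segregating=True)
            for i in range(50_000, 50_010)
        ] + [
            AlleleCount("chr1", i, "A", 8, 0, None, 30, 0, segregating=False)
            for i in range(60_000, 60_090)
        ]
        w = self._window(inside + outside)
        seg = MCRSegment("chr1", 0, 5_000, 3.0, 5)
        splits, summary = mcr_window_overlap([seg], [w], 18)
        assert splits[0].theta_inside == pytest.approx(
            theta_w_pool(20, DepthSpectrum({8: 100}), 18)
        )
        assert summary["outside_in_mcr_windows"] == pytest.approx(
            theta_w_pool(10, DepthSpectrum({8: 100}), 18)
        )
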