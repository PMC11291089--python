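"""Pileup columns, poorly-supported flagging, break detection/classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from igqc.config import Thresholds
from igqc.error_metrics import (
    CoverageBreak,
    LocusPileup,
    basepair_mismatch_rate,
    build_pileup,
    classify_break,
    detect_coverage_breaks,
    flag_poorly_supported,
    runs_from_mask,
)
from igqc.io_formats import LocusInterval, ReferenceAssembly
from igqc.read_stats import ReadAlignmentStats, collect_read_stats

from conftest import naive_pileup_counts


def _read(start, end, poor=False, mapq=60, mismatches=(), deletions=()):
    s = ReadAlignmentStats(
        read_id=f"r{start}", contig="c", start=start, end=end, mapq=mapq,
        aligned_length=end - start, substitutions=len(mismatches),
        soft_clip_bases=0, hard_clip_bases=0, indel_events=len(deletions),
        poorly_aligned=poor,
        mismatch_positions=np.asarray(mismatches, dtype=np.int64),
        deletion_spans=list(deletions),
    )
    return s


def _pileup_from_depth(depth, contig="c", spans=()):
    depth = np.asarray(depth)
    L = depth.size
    z = np.zeros(L, dtype=int)
    locus = LocusInterval(contig, 0, L, "IGH")
    return LocusPileup(locus, depth, z.copy(), z.copy(), z.copy(),
                       depth.copy(), z.copy(), z.copy(), list(spans))


class TestPileup:
    def test_single_matching_read(self):
        locus = LocusInterval("c", 0, 100, "IGH")
        pile = build_pileup([_read(20, 60)], locus)
        assert pile.depth[20:60].min() == 1 and pile.depth[20:60].max() == 1
        assert pile.depth[:20].max() == 0 and pile.depth[60:].max() == 0
        assert pile.delta.sum() == 0 and pile.e_count.sum() == 0

    def test_thirteen_reads_three_mismatching(self):
        """13 covering reads, 3 with a non-reference base: 76.9% support."""
        locus = LocusInterval("c", 0, 50, "IGH")
        reads = [_read(0, 50, mismatches=[25] if i < 3 else []) for i in range(13)]
        pile = build_pileup(reads, locus)
        col = pile.column(25)
        assert (col.depth, col.delta) == (13, 3)
        assert round(100 * col.support_fraction, 1) == 76.9

    def test_deleted_position_counts_depth_not_delta(self):
        locus = LocusInterval("c", 0, 40, "IGH")
        pile = build_pileup([_read(0, 40, deletions=[(10, 15)])], locus)
        assert pile.depth[12] == 1
        assert pile.delta[12] == 0
        assert pile.deleted[12] == 1
        # conservation: delta + matching + deleted = depth
        matching = pile.depth - pile.delta - pile.deleted
        assert (matching >= 0).all()

    def test_mapq_bins_sum_to_depth(self):
        locus = LocusInterval("c", 0, 30, "IGH")
        reads = [_read(0, 30, mapq=q) for q in (60, 60, 30, 0)]
        pile = build_pileup(reads, locus)
        assert (pile.mapq60 + pile.mapq_mid + pile.mapq0 == pile.depth).all()
        assert pile.mapq0[5] == 1 and pile.mapq_mid[5] == 1

    def test_mapq_min_filter(self):
        locus = LocusInterval("c", 0, 30, "IGH")
        reads = [_read(0, 30, mapq=0), _read(0, 30, mapq=60)]
        pile = build_pileup(reads, locus, Thresholds(mapq_min=1))
        assert pile.depth.max() == 1

    def test_empty_stream_all_zero(self):
        pile = build_pileup([], LocusInterval("c", 0, 10, "IGH"))
        assert pile.depth.sum() == 0 and len(pile) == 10

    def test_fixture_equals_naive_recount(self, small_clean_fixture, thresholds):
        """Vectorized pileup equals per-position Python recount."""
        fx = small_clean_fixture
        locus = LocusInterval("hap2", 0, 30_000, "IGH", "hap2")
        records = [s for s in fx.alignments if s.reference_name == "hap2"]
        stats, _ = collect_read_stats(records, fx.assembly, thresholds)
        pile = build_pileup(stats, locus, thresholds)
        naive = naive_pileup_counts(
            records, fx.evaluated.contigs["hap2"], locus, thresholds.theta
        )
        for key in ("depth", "delta", "e_count", "deleted", "mapq60", "mapq_mid", "mapq0"):
            assert np.array_equal(getattr(pile, key), np.asarray(naive[key])), key


class TestFlagging:
    @pytest.mark.parametrize("n_poor,expected", [(6, True), (5, False)],
                             ids=["six-flagged", "five-boundary-not"])
    def test_strict_threshold(self, n_poor, expected):
        locus = LocusInterval("c", 0, 20, "IGH")
        reads = [_read(0, 20, poor=i < n_poor) for i in range(10)]
        track = flag_poorly_supported(build_pileup(reads, locus), 5)
        assert (10 in track.positions) is expected

    def test_adjacent_positions_merge(self):
        pile = _pileup_from_depth([0] * 30)
        pile.e_count[5:12] = 6
        pile.e_count[20:22] = 7
        track = flag_poorly_supported(pile, 5)
        assert track.intervals == [(5, 12), (20, 22)]
        assert track.positions.size == 9

    def test_flags_monotone_in_theta(self, small_deletion_fixture):
        """Lowering theta can only add poorly aligned reads, hence flags."""
        fx = small_deletion_fixture
        locus = LocusInterval("hap1", 0, 30_000, "IGH", "hap1")
        records = [s for s in fx.alignments if s.reference_name == "hap1"]
        flagged = {}
        for theta in (0.01, 0.005):
            stats, _ = collect_read_stats(
                records, fx.assembly, Thresholds(theta=theta)
            )
            pile = build_pileup(stats, locus)
            flagged[theta] = set(flag_poorly_supported(pile, 5).positions.tolist())
        assert flagged[0.01] <= flagged[0.005]
        assert flagged[0.01]  # deletion fixture does produce flags


class TestBasepairRate:
    def test_ratios_and_missing(self):
        pile = _pileup_from_depth([30, 12, 0])
        pile.delta[:] = [0, 4, 0]
        rate = basepair_mismatch_rate(pile)
        assert rate[0] == 0.0
        assert rate[1] == pytest.approx(1 / 3)
        assert np.isnan(rate[2])


class TestBreaks:
    def test_depth_track_example(self):
        brks = detect_coverage_breaks(_pileup_from_depth([5, 5, 0, 0, 1, 5]), 2)
        assert [(b.start, b.end, b.min_depth) for b in brks] == [(2, 5, 0)]
        assert brks[0].length == 3

    def test_no_breaks_above_threshold(self):
        assert detect_coverage_breaks(_pileup_from_depth([3, 4, 5, 3]), 2) == []

    @pytest.mark.parametrize("depth,inside", [(2, True), (3, False)],
                             ids=["depth2-inside", "depth3-outside"])
    def test_threshold_boundary(self, depth, inside):
        brks = detect_coverage_breaks(_pileup_from_depth([9, depth, 9]), 2)
        assert bool(brks) is inside

    def test_spanning_reads_counted(self):
        pile = _pileup_from_depth([0, 1, 1, 0], spans=[(0, 4), (1, 3)])
        (brk,) = detect_coverage_breaks(pile, 2)
        assert brk.spanning_reads == 1  # only the 0-4 read spans 0-4

    def test_category_priority(self):
        asm = ReferenceAssembly(
            contigs={"c": "A" * 40_000 + "N" * 100 + "A" * 40_000}
        )
        n_gap = CoverageBreak("c", 39_990, 40_150, 0, 0)
        assert classify_break(n_gap, asm) == "n_gap"
        zero = CoverageBreak("c", 20_000, 20_050, 0, 0)
        assert classify_break(zero, asm) == "zero_coverage"
        low = CoverageBreak("c", 20_000, 20_050, 1, 0)
        assert classify_break(low, asm) == "low_coverage"
        end = CoverageBreak("c", 10, 40, 0, 0)
        assert classify_break(end, asm) == "contig_end"

    def test_elevated_coverage_annotation(self):
        pile = _pileup_from_depth([30] * 90 + [100] * 10)
        mask = pile.elevated_mask(2.0)
        assert mask[95] and not mask[10]


class TestRunExtraction:
    @given(st.lists(st.booleans(), max_size=200), st.integers(0, 1000))
    def test_runs_reconstruct_mask(self, bits, offset):
        mask = np.asarray(bits, dtype=bool)
        runs = runs_from_mask(mask, offset)
        rebuilt = np.zeros(mask.size, dtype=bool)
        for s, e in runs:
            assert s < e
            rebuilt[s - offset : e - offset] = True
        assert np.array_equal(rebuilt, mask)
        # maximality: no two runs adjacent
        for (_, e1), (s2, _) in zip(runs, runs[1:]):
            assert s2 > e1
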