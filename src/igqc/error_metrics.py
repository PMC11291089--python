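"""Per-position support metrics and coverage-break detection.

Two complementary views of assembly support are computed over a locus:

* read-oriented: E_j = number of reads covering position j whose whole-read
  mismatch rate e_r exceeds theta.  A position is poorly supported when
  E_j > min_bad_reads (default 5, strict).  Clusters of such positions are
  the signature of sequence missing from the assembly — the reads have
  nowhere better to go, so they pile up on the closest homolog with
  elevated coverage and high mismatch.
* basepair-oriented: delta_j = number of covering reads whose base at j
  differs from the assembly base; support fraction = (depth - delta_j)/depth.

Coverage breaks are maximal runs of positions with depth at or below
break_threshold (default 2 reads).  They are categorized by reference
context in deterministic priority order: n_gap (overlaps an N-run) >
contig_end (within end_margin of a contig boundary) > zero_coverage >
low_coverage.

A read deleted at position j still counts toward depth there (its
alignment spans j) but contributes neither match nor mismatch, so depth =
matches + delta + deleted at every column and a break always means "no
read spans here".  Reads of every MAPQ, including 0, contribute to all
counts — ambiguous placement in repeats is reported via the MAPQ bins, not
treated as an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .config import Thresholds
from .io_formats import LocusInterval, ReferenceAssembly
from .read_stats import ReadAlignmentStats

BREAK_CATEGORIES = ("n_gap", "contig_end", "zero_coverage", "low_coverage")


@dataclass
class PileupColumn:
    contig: str
    position: int  # 0-based
    depth: int
    delta: int
    e_count: int
    deleted: int
    mapq60: int
    mapq_mid: int
    mapq0: int

    @property
    def support_fraction(self) -> float | None:
        if self.depth == 0:
            return None
        return (self.depth - self.delta) / self.depth


@dataclass
class LocusPileup:
    """Column-wise metric arrays over one locus interval.

    Arrays are indexed by offset from ``locus.start``.  Iterating yields
    PileupColumn views.
    """

    locus: LocusInterval
    depth: np.ndarray
    delta: np.ndarray
    e_count: np.ndarray
    deleted: np.ndarray
    mapq60: np.ndarray
    mapq_mid: np.ndarray
    mapq0: np.ndarray
    #: reference spans of the contributing reads (for spanning-read counts)
    read_spans: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return self.locus.length

    def column(self, position: int) -> PileupColumn:
        i = position - self.locus.start
        return PileupColumn(
            self.locus.contig,
            position,
            int(self.depth[i]),
            int(self.delta[i]),
            int(self.e_count[i]),
            int(self.deleted[i]),
            int(self.mapq60[i]),
            int(self.mapq_mid[i]),
            int(self.mapq0[i]),
        )

    def __iter__(self) -> Iterator[PileupColumn]:
        for pos in range(self.locus.start, self.locus.end):
            yield self.column(pos)

    def support_fraction(self) -> np.ndarray:
        """(depth - delta) / depth, NaN where depth is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.depth > 0, (self.depth - self.delta) / self.depth, np.nan
            )

    def median_depth(self) -> float:
        return float(np.median(self.depth))

    def elevated_mask(self, factor: float = 2.0) -> np.ndarray:
        """Columns with depth > factor * median locus depth (annotation only)."""
        return self.depth > factor * self.median_depth()


@dataclass
class PositionFlagTrack:
    """Poorly supported positions of a locus, plus their merged intervals."""

    locus: LocusInterval
    positions: np.ndarray  # sorted absolute positions
    intervals: list[tuple[int, int]]  # maximal merged runs, half-open

    @property
    def flagged_fraction(self) -> float:
        return self.positions.size / self.locus.length


@dataclass
class CoverageBreak:
    contig: str
    start: int  # 0-based half-open
    end: int
    min_depth: int
    spanning_reads: int
    category: str = "low_coverage"

    @property
    def length(self) -> int:
        return self.end - self.start

    def region_string(self) -> str:
        return f"{self.contig}:{self.start + 1}-{self.end}"


def runs_from_mask(mask: np.ndarray, offset: int = 0) -> list[tuple[int, int]]:
    """Maximal half-open runs of True in a boolean mask, shifted by offset."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s) + offset, int(e) + offset) for s, e in zip(starts, ends)]


def build_pileup(
    reads: list[ReadAlignmentStats],
    locus: LocusInterval,
    thresholds: Thresholds | None = None,
) -> LocusPileup:
    """Accumulate per-position depth, delta, E-counts and MAPQ bins.

    ``reads`` carry their own mismatch positions and deletion spans (from
    read_stats), so no alignment file access happens here.  Deleted
    positions count toward depth; inserted bases anchor to no position.
    """
    thr = thresholds or Thresholds()
    L = locus.length
    off = locus.start
    depth = np.zeros(L, dtype=np.int32)
    delta = np.zeros(L, dtype=np.int32)
    e_count = np.zeros(L, dtype=np.int32)
    deleted = np.zeros(L, dtype=np.int32)
    bins = {
        "mapq60": np.zeros(L, dtype=np.int32),
        "mapq_mid": np.zeros(L, dtype=np.int32),
        "mapq0": np.zeros(L, dtype=np.int32),
    }
    # difference arrays for the span-shaped tracks
    ddiff = np.zeros(L + 1, dtype=np.int32)
    ediff = np.zeros(L + 1, dtype=np.int32)
    bdiff = {k: np.zeros(L + 1, dtype=np.int32) for k in bins}
    spans: list[tuple[int, int]] = []

    for r in reads:
        if r.mapq < thr.mapq_min:
            continue
        s = max(r.start, locus.start) - off
        e = min(r.end, locus.end) - off
        if s >= e:
            continue
        spans.append((r.start, r.end))
        ddiff[s] += 1
        ddiff[e] -= 1
        if r.poorly_aligned:
            ediff[s] += 1
            ediff[e] -= 1
        key = "mapq60" if r.mapq >= 60 else ("mapq0" if r.mapq == 0 else "mapq_mid")
        bdiff[key][s] += 1
        bdiff[key][e] -= 1
        if r.mismatch_positions.size:
            mp = r.mismatch_positions
            mp = mp[(mp >= locus.start) & (mp < locus.end)] - off
            np.add.at(delta, mp, 1)
        for ds, de in r.deletion_spans:
            ds = max(ds, locus.start) - off
            de = min(de, locus.end) - off
            if ds < de:
                deleted[ds:de] += 1

    depth += np.cumsum(ddiff[:-1])
    e_count += np.cumsum(ediff[:-1])
    for k in bins:
        bins[k] += np.cumsum(bdiff[k][:-1])
    return LocusPileup(
        locus, depth, delta, e_count, deleted,
        bins["mapq60"], bins["mapq_mid"], bins["mapq0"], spans,
    )


def flag_poorly_supported(
    pileup: LocusPileup, min_bad_reads: int = 5
) -> PositionFlagTrack:
    """Positions with E_j > min_bad_reads (strict), merged into intervals."""
    mask = pileup.e_count > min_bad_reads
    positions = np.flatnonzero(mask) + pileup.locus.start
    intervals = runs_from_mask(mask, pileup.locus.start)
    return PositionFlagTrack(pileup.locus, positions, intervals)


def basepair_mismatch_rate(pileup: LocusPileup) -> np.ndarray:
    """delta_j / depth_j; NaN (missing, not zero) where depth is 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(pileup.depth > 0, pileup.delta / pileup.depth, np.nan)


def detect_coverage_breaks(
    pileup: LocusPileup,
    break_threshold: int = 2,
    min_break_len: int = 1,
) -> list[CoverageBreak]:
    """Maximal runs with depth <= break_threshold, with spanning-read counts."""
    mask = pileup.depth <= break_threshold
    breaks = []
    for s, e in runs_from_mask(mask, pileup.locus.start):
        if e - s < min_break_len:
            continue
        spanning = sum(1 for rs, re_ in pileup.read_spans if rs <= s and re_ >= e)
        min_depth = int(pileup.depth[s - pileup.locus.start : e - pileup.locus.start].min())
        breaks.append(
            CoverageBreak(pileup.locus.contig, s, e, min_depth, spanning)
        )
    return breaks


def classify_break(
    brk: CoverageBreak,
    assembly: ReferenceAssembly,
    end_margin: int = 5_000,
) -> str:
    """Deterministic category priority: n_gap > contig_end > zero > low."""
    if assembly.n_runs_in(brk.contig, brk.start, brk.end):
        return "n_gap"
    contig_len = len(assembly.contigs[brk.contig])
    if brk.start < end_margin or brk.end > contig_len - end_margin:
        return "contig_end"
    if brk.min_depth == 0:
        return "zero_coverage"
    return "low_coverage"


def classify_breaks(
    breaks: list[CoverageBreak],
    assembly: ReferenceAssembly,
    end_margin: int = 5_000,
) -> list[CoverageBreak]:
    for brk in breaks:
        brk.category = classify_break(brk, assembly, end_margin)
    return breaks
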