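"""Per-read alignment statistics.

For a read r aligned to assembly G, the substitution count d(r, G) is the
number of aligned positions where the read base differs from the assembly
base, and the mismatch rate e_r = d / n(r) with n(r) the ALIGNED length
(read bases in M/=/X columns).  Clips and indels are tracked as separate
channels and never enter d or n(r); positions where the assembly base is N
are excluded from d (comparison against N is undefined).

A read is "poorly aligned" when e_r strictly exceeds the threshold theta
(default 0.01): HiFi sequencing error is well below 1%, so a higher rate
points at the assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .config import Thresholds
from .io_formats import FormatError, ReferenceAssembly

# pysam CIGAR op codes
_MATCH_OPS = frozenset((0, 7, 8))  # M, =, X
_INS, _DEL, _SOFT, _HARD = 1, 2, 4, 5


class SkippedRecord(FormatError):
    """Record inconsistent with its own CIGAR/sequence; skip with a warning."""


@dataclass
class ReadAlignmentStats:
    read_id: str
    contig: str
    start: int  # 0-based half-open reference span
    end: int
    mapq: int
    aligned_length: int
    substitutions: int
    soft_clip_bases: int
    hard_clip_bases: int
    indel_events: int
    poorly_aligned: bool = False
    #: reference positions of substitutions (for the pileup delta track)
    mismatch_positions: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    #: reference half-open spans deleted in the read (depth but no base)
    deletion_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def mismatch_rate(self) -> float:
        return self.substitutions / self.aligned_length if self.aligned_length else 0.0

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and self.end > start


def _cigar_channels(record: pysam.AlignedSegment, indel_min_len: int):
    aligned = soft = hard = indels = 0
    del_spans: list[tuple[int, int]] = []
    rpos = record.reference_start
    for op, length in record.cigartuples:
        if op in _MATCH_OPS:
            aligned += length
            rpos += length
        elif op == _INS:
            if length >= indel_min_len:
                indels += 1
        elif op == _DEL:
            if length >= indel_min_len:
                indels += 1
            del_spans.append((rpos, rpos + length))
            rpos += length
        elif op == _SOFT:
            soft += length
        elif op == _HARD:
            hard += length
        elif op == 3:  # N skip
            rpos += length
    return aligned, soft, hard, indels, del_spans


def _substitutions_md(record: pysam.AlignedSegment) -> np.ndarray:
    """Reference positions of substitutions via the MD tag (fast path)."""
    positions = [
        rpos
        for _qpos, rpos, ref in record.get_aligned_pairs(with_seq=True)
        if rpos is not None
        and _qpos is not None
        and ref is not None
        and ref.islower()
        and ref.upper() != "N"
    ]
    return np.asarray(positions, dtype=np.int64)


def _substitutions_walk(
    record: pysam.AlignedSegment, reference: str
) -> np.ndarray:
    """Base-by-base CIGAR walk against the contig sequence (fallback path)."""
    query = record.query_sequence
    positions = []
    for qpos, rpos in record.get_aligned_pairs(matches_only=True):
        ref_base = reference[rpos]
        if ref_base != "N" and query[qpos] != ref_base:
            positions.append(rpos)
    return np.asarray(positions, dtype=np.int64)


def read_mismatch_rate(
    record: pysam.AlignedSegment,
    assembly: ReferenceAssembly | None = None,
    thresholds: Thresholds | None = None,
) -> ReadAlignmentStats:
    """Compute ReadAlignmentStats for one mapped primary alignment.

    Substitutions come from MD-derived aligned pairs when the tag is
    present, else from a base-by-base walk against ``assembly`` (which is
    then required).
    """
    thr = thresholds or Thresholds()
    if record.is_unmapped:
        raise FormatError(f"read {record.query_name}: unmapped record rejected")
    if record.cigartuples is None:
        raise SkippedRecord(f"read {record.query_name}: no CIGAR")
    if record.query_sequence is not None:
        expected = sum(
            ln for op, ln in record.cigartuples if op in (_INS, _SOFT) or op in _MATCH_OPS
        )
        if len(record.query_sequence) != expected:
            raise SkippedRecord(
                f"read {record.query_name}: sequence length "
                f"{len(record.query_sequence)} disagrees with CIGAR ({expected})"
            )

    aligned, soft, hard, indels, del_spans = _cigar_channels(record, thr.indel_min_len)

    if record.has_tag("MD"):
        mismatch_pos = _substitutions_md(record)
    else:
        if assembly is None:
            raise FormatError(
                f"read {record.query_name}: no MD tag and no assembly provided"
            )
        mismatch_pos = _substitutions_walk(
            record, assembly.contigs[record.reference_name]
        )

    denom = aligned
    if thr.mismatch_denominator == "full":
        denom = record.infer_read_length() or aligned

    subs = int(mismatch_pos.size)
    stats = ReadAlignmentStats(
        read_id=record.query_name,
        contig=record.reference_name,
        start=record.reference_start,
        end=record.reference_end,
        mapq=record.mapping_quality,
        aligned_length=denom,
        substitutions=subs,
        soft_clip_bases=soft,
        hard_clip_bases=hard,
        indel_events=indels,
        mismatch_positions=mismatch_pos,
        deletion_spans=del_spans,
    )
    stats.poorly_aligned = classify_read(stats, thr.theta)
    return stats


def classify_read(stats: ReadAlignmentStats, theta: float = 0.01) -> bool:
    """Poorly aligned iff e_r > theta, strict."""
    return stats.mismatch_rate > theta


def collect_read_stats(
    records,
    assembly: ReferenceAssembly | None = None,
    thresholds: Thresholds | None = None,
) -> tuple[list[ReadAlignmentStats], int]:
    """Run read_mismatch_rate over a record stream; returns (stats, n_skipped)."""
    out: list[ReadAlignmentStats] = []
    skipped = 0
    for rec in records:
        try:
            out.append(read_mismatch_rate(rec, assembly, thresholds))
        except SkippedRecord:
            skipped += 1
    return out, skipped


@dataclass
class ReadSummary:
    """Cohort-level read statistics backing the summary panels."""

    n_reads: int
    mapq_values: np.ndarray
    soft_clip_values: np.ndarray
    hard_clip_values: np.ndarray
    mismatch_rates: np.ndarray
    indel_counts: np.ndarray
    fraction_soft_clipped: float
    fraction_poorly_aligned: float

    def mapq_histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.mapq_values, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def as_row(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "fraction_soft_clipped": round(self.fraction_soft_clipped, 4),
            "fraction_poorly_aligned": round(self.fraction_poorly_aligned, 4),
            "mean_mismatch_rate": (
                float(self.mismatch_rates.mean()) if self.n_reads else 0.0
            ),
            "mean_indel_events": (
                float(self.indel_counts.mean()) if self.n_reads else 0.0
            ),
        }


def summarize_reads(stats: list[ReadAlignmentStats]) -> ReadSummary:
    """Aggregate per-read statistics; an empty cohort yields a zeroed summary."""
    if not stats:
        empty = np.empty(0)
        return ReadSummary(0, empty, empty, empty, empty, empty, 0.0, 0.0)
    mapq = np.array([s.mapq for s in stats])
    soft = np.array([s.soft_clip_bases for s in stats])
    hard = np.array([s.hard_clip_bases for s in stats])
    rates = np.array([s.mismatch_rate for s in stats])
    indels = np.array([s.indel_events for s in stats])
    return ReadSummary(
        n_reads=len(stats),
        mapq_values=mapq,
        soft_clip_values=soft,
        hard_clip_values=hard,
        mismatch_rates=rates,
        indel_counts=indels,
        fraction_soft_clipped=float((soft > 0).mean()),
        fraction_poorly_aligned=float(
            np.mean([s.poorly_aligned for s in stats])
        ),
    )


def read_stats_frame(stats: list[ReadAlignmentStats]) -> "pd.DataFrame":
    """One row per read, for the audit TSV."""
    import pandas as pd

    return pd.DataFrame(
        {
            "read_id": [s.read_id for s in stats],
            "contig": [s.contig for s in stats],
            "start": [s.start for s in stats],
            "end": [s.end for s in stats],
            "mapq": [s.mapq for s in stats],
            "aligned_length": [s.aligned_length for s in stats],
            "substitutions": [s.substitutions for s in stats],
            "mismatch_rate": [round(s.mismatch_rate, 6) for s in stats],
            "soft_clip_bases": [s.soft_clip_bases for s in stats],
            "hard_clip_bases": [s.hard_clip_bases for s in stats],
            "indel_events": [s.indel_events for s in stats],
            "poorly_aligned": [s.poorly_aligned for s in stats],
        }
    )
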