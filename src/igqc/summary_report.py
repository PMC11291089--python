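"""Per-locus quality calls and cross-species aggregation.

A locus (per species and locus class, union of its haplotype intervals)
receives two boolean flags:

* mismatch_flag — at least one merged poorly-supported interval of length
  >= ``call_min_flag_interval`` (default 100 bp), or flagged positions
  covering >= ``call_min_flag_fraction`` (default 0.5%) of the locus.
  The floors keep isolated single-position flags from condemning a locus;
  they are calibrated so an error-free simulation yields "good".
* break_flag — at least one coverage break of length >=
  ``call_min_break_len`` (default 10 bp) whose category is not contig_end.

The category is mismatch > break > good by precedence.  Cross-species
aggregation counts per (locus class, haplotype resolution) group.  Because
a species can carry both flags, the published style of summary counts the
mismatch and break columns non-exclusively (their sum can exceed the group
total); the aggregator also offers an exclusive mode using the precedence
category.  Percentages are reported to 0.1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .config import Thresholds
from .error_metrics import CoverageBreak, PositionFlagTrack
from .io_formats import FormatError

RESOLUTIONS = ("resolved", "unresolved")


def _pct(count: int, total: int) -> float:
    """Percentage to 0.1, rounding halves up (the convention of printed
    summary tables, where 15/48 appears as 31.3%)."""
    return math.floor(1000.0 * count / total + 0.5) / 10.0


@dataclass
class LocusQualityCall:
    species: str
    locus_class: str
    haplotype_resolution: str  # resolved | unresolved
    mismatch_flag: bool
    break_flag: bool

    @property
    def category(self) -> str:
        if self.mismatch_flag:
            return "mismatch"
        if self.break_flag:
            return "break"
        return "good"

    @property
    def any_error(self) -> bool:
        return self.mismatch_flag or self.break_flag


def call_locus(
    flag_tracks: list[PositionFlagTrack],
    breaks: list[CoverageBreak],
    species: str,
    locus_class: str,
    haplotype_resolution: str,
    thresholds: Thresholds | None = None,
) -> LocusQualityCall:
    """Combine per-haplotype evidence into one locus-level quality call."""
    thr = thresholds or Thresholds()
    if not flag_tracks:
        raise FormatError("call_locus requires at least one flag track")
    total_len = sum(t.locus.length for t in flag_tracks)
    flagged = sum(int(t.positions.size) for t in flag_tracks)
    longest = max(
        (e - s for t in flag_tracks for s, e in t.intervals), default=0
    )
    mismatch_flag = (
        longest >= thr.call_min_flag_interval
        or flagged >= thr.call_min_flag_fraction * total_len
    )
    break_flag = any(
        b.length >= thr.call_min_break_len and b.category != "contig_end"
        for b in breaks
    )
    return LocusQualityCall(
        species, locus_class, haplotype_resolution, mismatch_flag, break_flag
    )


def calls_frame(calls: list[LocusQualityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [c.species for c in calls],
            "locus": [c.locus_class for c in calls],
            "resolution": [c.haplotype_resolution for c in calls],
            "mismatch_flag": [c.mismatch_flag for c in calls],
            "break_flag": [c.break_flag for c in calls],
        }
    )


def reconstruct_calls(
    locus: str,
    resolution: str,
    total: int,
    n_mismatch: int,
    n_break: int,
    n_good: int,
    species_prefix: str = "sp",
) -> pd.DataFrame:
    """Build a per-species calls table matching published per-group counts.

    When the three column counts exceed the group total, the excess is the
    number of species carrying both flags; those rows are emitted first.
    Lets summary arithmetic be reproduced from printed counts alone.
    """
    n_any = total - n_good
    overlap = n_mismatch + n_break - n_any
    if overlap < 0 or overlap > min(n_mismatch, n_break) or n_any < 0:
        raise FormatError(
            f"inconsistent counts for {locus}/{resolution}: "
            f"{n_mismatch}+{n_break}+{n_good} vs total {total}"
        )
    rows = []
    for i in range(total):
        mismatch = i < n_mismatch
        brk = i < overlap or n_mismatch <= i < n_mismatch + (n_break - overlap)
        rows.append(
            {
                "species": f"{species_prefix}_{locus}_{resolution}_{i:03d}",
                "locus": locus,
                "resolution": resolution,
                "mismatch_flag": mismatch,
                "break_flag": brk,
            }
        )
    return pd.DataFrame(rows)


def aggregate_species(
    calls: pd.DataFrame | list[LocusQualityCall],
    mode: str = "non-exclusive",
) -> pd.DataFrame:
    """Summary counts/percentages per (locus, resolution) plus any-error rows.

    ``mode="non-exclusive"`` counts every raised flag (a both-flag species
    appears in both columns); ``"exclusive"`` counts the precedence
    category only.  Good is always "neither flag".  Output rows with
    resolution ``"all"`` aggregate a locus across resolutions and carry the
    any-error count.
    """
    if isinstance(calls, list):
        calls = calls_frame(calls)
    required = {"species", "locus", "resolution", "mismatch_flag", "break_flag"}
    missing = required - set(calls.columns)
    if missing:
        raise FormatError(f"calls table missing columns: {sorted(missing)}")
    if calls.duplicated(["species", "locus"]).any():
        dup = calls[calls.duplicated(["species", "locus"])].iloc[0]
        raise FormatError(f"duplicate call for ({dup['species']}, {dup['locus']})")
    if mode not in ("non-exclusive", "exclusive"):
        raise FormatError(f"unknown counting mode {mode!r}")

    rows = []
    for (locus, resolution), grp in sorted(
        calls.groupby(["locus", "resolution"], sort=True)
    ):
        total = len(grp)
        mm = grp["mismatch_flag"].astype(bool)
        bb = grp["break_flag"].astype(bool)
        if mode == "non-exclusive":
            n_mm, n_bk = int(mm.sum()), int(bb.sum())
        else:
            n_mm = int(mm.sum())
            n_bk = int((bb & ~mm).sum())
        n_good = int((~mm & ~bb).sum())
        rows.append(
            {
                "locus": locus,
                "resolution": resolution,
                "total": total,
                "mismatch_n": n_mm,
                "mismatch_pct": _pct(n_mm, total),
                "break_n": n_bk,
                "break_pct": _pct(n_bk, total),
                "good_n": n_good,
                "good_pct": _pct(n_good, total),
                "any_error_n": total - n_good,
                "any_error_pct": _pct((total - n_good), total),
            }
        )
    for locus, grp in sorted(calls.groupby("locus", sort=True)):
        total = len(grp)
        mm = grp["mismatch_flag"].astype(bool)
        bb = grp["break_flag"].astype(bool)
        n_good = int((~mm & ~bb).sum())
        n_any = total - n_good
        n_mm = int(mm.sum())
        n_bk = int(bb.sum()) if mode == "non-exclusive" else int((bb & ~mm).sum())
        rows.append(
            {
                "locus": locus,
                "resolution": "all",
                "total": total,
                "mismatch_n": n_mm,
                "mismatch_pct": _pct(n_mm, total),
                "break_n": n_bk,
                "break_pct": _pct(n_bk, total),
                "good_n": n_good,
                "good_pct": _pct(n_good, total),
                "any_error_n": n_any,
                "any_error_pct": _pct(n_any, total),
            }
        )
    return pd.DataFrame(rows)
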