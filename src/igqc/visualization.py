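"""Diagnostic plots: coverage/MAPQ tracks, support overlays, read panels.

Conventions: depth is stacked by MAPQ bin (60 / 1-59 / 0); poorly
supported intervals are drawn as translucent red spans and coverage breaks
as purple bars; the heatmap strip above the support track darkens with the
per-bin count of weak positions (support fraction <= 0.8).  Haplotype
series use blue (primary / hap1) and yellow (alternate / hap2).

Every overlay drawn is also written to a sidecar TSV with the exact
intervals, so tests (and users) can verify plots against tables without
pixel comparisons.  Rendering is deterministic: fixed figure geometry, no
timestamps in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import Thresholds
from .error_metrics import CoverageBreak, LocusPileup, PositionFlagTrack
from .io_formats import FormatError, LocusInterval, write_tsv
from .read_stats import ReadSummary

HAPLOTYPE_COLORS = ("#4878b0", "#e0a23c")  # blue / yellow
FLAG_COLOR = "#d62728"
BREAK_COLOR = "#7b3fa0"


@dataclass
class PlotSpec:
    path: Path
    format: str = "png"
    heatmap_bin: int = 10_000
    figsize: tuple[float, float] = (12.0, 6.0)
    dpi: int = 100
    support_min: float = 0.8

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.heatmap_bin < 1:
            raise FormatError("heatmap bin width must be >= 1 bp")


def _save(fig, spec: PlotSpec) -> Path:
    out = spec.path.with_suffix(f".{spec.format}")
    out.parent.mkdir(parents=True, exist_ok=True)
    meta = {"Date": None} if spec.format == "svg" else None
    fig.savefig(out, dpi=spec.dpi, metadata=meta)
    plt.close(fig)
    return out


def weak_position_bins(
    pileup: LocusPileup, bin_width: int, support_min: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin counts of covered positions with support <= support_min."""
    support = pileup.support_fraction()
    weak = (pileup.depth > 0) & (support <= support_min)
    n_bins = int(np.ceil(pileup.locus.length / bin_width))
    edges = pileup.locus.start + np.arange(n_bins + 1) * bin_width
    edges[-1] = pileup.locus.end
    idx = np.arange(pileup.locus.length) // bin_width
    counts = np.bincount(idx[weak], minlength=n_bins)
    return edges, counts


def plot_locus_diagnostics(
    pileup: LocusPileup,
    flag_track: PositionFlagTrack,
    breaks: list[CoverageBreak],
    spec: PlotSpec,
) -> tuple[Path, Path]:
    """Render the per-locus diagnostic panel; returns (image, sidecar TSV)."""
    if pileup.locus.length == 0:
        raise FormatError("empty metrics; nothing to plot")
    locus = pileup.locus
    x = np.arange(locus.start, locus.end)

    fig, (ax_cov, ax_heat, ax_sup) = plt.subplots(
        3, 1, figsize=spec.figsize, sharex=True,
        gridspec_kw={"height_ratios": [4, 0.5, 3]},
    )
    # panel i: depth stacked by MAPQ bin
    base = np.zeros(locus.length)
    for track, color, label in (
        (pileup.mapq60, "#2c7fb8", "MAPQ 60"),
        (pileup.mapq_mid, "#7fcdbb", "MAPQ 1-59"),
        (pileup.mapq0, "#bdbdbd", "MAPQ 0"),
    ):
        ax_cov.fill_between(x, base, base + track, color=color, label=label, lw=0)
        base = base + track
    ax_cov.set_ylabel("depth")
    ax_cov.legend(loc="upper right", fontsize=8)
    ax_cov.set_title(f"{locus.locus_class} {locus.region_string()}")

    # heatmap strip: weak positions per bin
    edges, counts = weak_position_bins(pileup, spec.heatmap_bin, spec.support_min)
    ax_heat.imshow(
        counts[np.newaxis, :],
        aspect="auto",
        cmap="Reds",
        extent=(locus.start, locus.end, 0, 1),
        vmin=0,
        vmax=max(1, counts.max()),
    )
    ax_heat.set_yticks([])
    ax_heat.set_ylabel("weak", rotation=0, ha="right", va="center", fontsize=8)

    # panel ii: support track with red flag spans and purple break bars
    support = pileup.support_fraction()
    ax_sup.plot(x, support * 100.0, color="#444444", lw=0.5)
    ax_sup.set_ylim(0, 105)
    ax_sup.set_ylabel("base support (%)")
    ax_sup.set_xlabel(f"position on {locus.contig} (0-based)")
    for s, e in flag_track.intervals:
        ax_sup.axvspan(s, e, color=FLAG_COLOR, alpha=0.3, lw=0)
    for brk in breaks:
        ax_sup.axvspan(brk.start, brk.end, color=BREAK_COLOR, alpha=0.6, lw=0)

    image = _save(fig, spec)

    overlay_rows = [
        {"kind": "flag", "contig": locus.contig, "start": s + 1, "end": e}
        for s, e in flag_track.intervals
    ] + [
        {
            "kind": f"break:{b.category}",
            "contig": b.contig,
            "start": b.start + 1,
            "end": b.end,
        }
        for b in breaks
    ] + [
        {
            "kind": "heatmap_bin",
            "contig": locus.contig,
            "start": int(edges[i]) + 1,
            "end": int(edges[i + 1]),
            "count": int(counts[i]),
        }
        for i in range(len(counts))
    ]
    sidecar = write_tsv(
        pd.DataFrame(overlay_rows),
        spec.path.with_suffix(".overlays.tsv"),
        ["# coordinates: 1-based inclusive"],
    )
    return image, sidecar


def plot_read_summaries(
    summaries: dict[str, ReadSummary], spec: PlotSpec
) -> Path:
    """Four panels (MAPQ, soft clips, mismatch rates, indels) per haplotype."""
    fig, axes = plt.subplots(2, 2, figsize=spec.figsize)
    panels = [
        ("mapq_values", "MAPQ", axes[0, 0]),
        ("soft_clip_values", "soft-clipped bases", axes[0, 1]),
        ("mismatch_rates", "read mismatch rate", axes[1, 0]),
        ("indel_counts", "indel events (>=2 bp)", axes[1, 1]),
    ]
    for i, (label, summary) in enumerate(sorted(summaries.items())):
        color = HAPLOTYPE_COLORS[i % len(HAPLOTYPE_COLORS)]
        for attr, title, ax in panels:
            values = getattr(summary, attr)
            if values.size:
                ax.hist(values, bins=30, alpha=0.6, color=color, label=label)
            ax.set_xlabel(title)
            ax.set_ylabel("reads")
    if axes[0, 0].get_legend_handles_labels()[1]:
        axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    return _save(fig, spec)


def plot_locus_lengths(loci: list[LocusInterval], spec: PlotSpec) -> tuple[Path, dict]:
    """Grouped bars of summed locus length per haplotype label.

    Returns the image path and the plotted totals (label -> bp), the data
    array behind the bars.
    """
    totals: dict[str, int] = {}
    for locus in loci:
        label = locus.haplotype_label or "unlabelled"
        totals[label] = totals.get(label, 0) + locus.length
    labels = sorted(totals)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(
        labels,
        [totals[k] / 1e6 for k in labels],
        color=[HAPLOTYPE_COLORS[i % 2] for i in range(len(labels))],
    )
    ax.set_ylabel("locus length (Mb)")
    fig.tight_layout()
    return _save(fig, spec), totals
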