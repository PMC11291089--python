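# Methods

## Model of assembly error evidence

`igqc` treats an assembly position as a hypothesis that every read
covering it should support. HiFi reads are accurate (< 0.5% substitution
error) and long (15–25 kb in production data), so three evidence channels
separate cleanly:

1. **Whole-read mismatch rate** e_r = d(r, G)/n(r), where d counts aligned
   columns at which read and assembly bases differ and n(r) is the number
   of read bases in M/=/X CIGAR columns. A read with e_r above θ = 0.01 is
   "poorly aligned": a rate several-fold above the sequencing error floor
   means the aligner could not find the read's true origin, usually
   because that origin is absent from the assembly. The per-position count
   E_j of poorly aligned covering reads, with the strict rule E_j > 5,
   flags positions where displaced reads pile up. Missing haplotype
   segments produce exactly this: reads from the lost segment map onto the
   retained homolog, raising E_j over a contiguous cluster and inflating
   depth ~2× there.
2. **Per-position disagreement** δ_j (covering reads whose base at j
   differs from G_j), reported as a support fraction (depth − δ)/depth.
   This is the channel that catches isolated consensus errors, and the one
   the gene-level "perfect support" rule uses.
3. **Coverage continuity.** Maximal runs of depth ≤ 2 are coverage breaks.
   Their interpretation depends on reference context, applied in
   deterministic priority order: overlap with an N-run (`n_gap`, a suspect
   scaffolding join), proximity to a contig boundary within 5 kb
   (`contig_end`, expected attrition), minimum depth 0 (`zero_coverage`),
   otherwise `low_coverage`. The categories are this package's own
   taxonomy, built from the reference-context evidence the metrics
   expose.

Multi-mapping reads (MAPQ 0) are never treated as errors: perfect
alignments placed arbitrarily between identical repeats or haplotype
copies are a property of the genome, not the assembly. They contribute to
depth and to δ/E like any other read and are surfaced through MAPQ bins
{60, 1–59, 0} in tables and plots; a `mapq_min` filter exists but defaults
to 0.

## Decision rules and tunable parameters

| parameter | default | meaning |
|---|---|---|
| θ (`theta`) | 0.01 | per-read mismatch-rate threshold, strict `>` |
| `min_bad_reads` | 5 | E_j must strictly exceed this to flag position j |
| `break_threshold` | 2 reads | depth at or below ⇒ inside a coverage break |
| `support_min` | 0.8 | per-position support a gene must strictly exceed |
| `gene_poor_read_max` | 5 | poor reads overlapping a gene, strict `>` |
| `indel_min_len` | 2 bp | minimum run length counted as an indel event |
| `end_margin` | 5 kb | contig-end window for break categorization |
| `coverage_high_factor` | 2.0 | depth > factor × median ⇒ "elevated" annotation |
| `call_min_flag_interval` | 100 bp | flagged-interval floor for a locus mismatch call |
| `call_min_flag_fraction` | 0.5% | flagged-fraction alternative floor |
| `call_min_break_len` | 10 bp | break-length floor for a locus break call |

Boundary semantics are strict everywhere: e_r = 0.01 exactly is not
poorly aligned, E_j = 5 is not flagged, depth 3 is outside a break,
support of exactly 80% is not perfect, and a gene overlapped by exactly 5
poor reads is not affected. n(r) is the aligned length, not the full read
length (configurable): clipped bases are a separate evidence channel, and
the aligned-length denominator keeps e_r ≤ 1 and insensitive to clipping.
Indels never contribute to d(r, G) — the distance is positionwise base
inequality — and are tracked as events of length ≥ 2 bp. Positions where
the assembly base is N are excluded from d (comparison against N is
undefined). A read deleted at position j still counts toward depth (its
alignment spans j) but toward neither match nor mismatch, so
depth = matches + δ + deleted holds at every column and a coverage break
always means "no read spans here".

The locus-level evidence floors (`call_min_*`) separate locus categories
from raw position flags; they are this package's own calibration, chosen
so that an error-free simulation yields "good" while the injected-defect
fixtures yield their expected categories, and are echoed into every
output header.

## Coordinates and tables

Internally everything is 0-based half-open; BED input is consumed
natively, 1-based-inclusive tables are shifted on load, and all
human-facing tables and region strings are 1-based inclusive with the
dialect recorded in a `#` header comment. A region string like
`scaffold_8:75432695-75440919` therefore denotes 8,225 bp. All thresholds
used in a run are echoed verbatim into each table header and the JSON run
manifest, and plots draw only intervals already present in the emitted
tables (with a sidecar TSV of drawn overlays for verification).

Per-read statistics are computed from the alignment records themselves,
not from an mpileup stream: mpileup carries no read identity, so E_j
cannot be derived from it. An mpileup text parser is provided for the
basepair-oriented path only, and doubles as an independent cross-check
against `samtools mpileup` in the test suite.

## Cross-species aggregation

A species/locus receives `mismatch_flag` and `break_flag` (breaks of
category `contig_end` never raise the flag) and the category
mismatch > break > good. Because both flags can be raised at once, the
aggregator counts the mismatch and break columns **non-exclusively** by
default — their sum may exceed the group total, matching the arithmetic of
published summary tables reconstructed from printed counts — with an
exclusive (precedence-category) mode available. Percentages are reported
to 0.1%, rounding halves up (15/48 → 31.3%). `reconstruct_calls` builds a
per-species flag table from printed per-group counts, placing the implied
overlap in both-flag species, so the summary arithmetic is reproducible
without any genome data.

## Synthetic fixtures

The generator emulates the structure that makes IG loci hard while
remaining desk-scale:

- a 100 kb haplotype (defaults; real IG loci are 1–2.5 Mb) carrying eight
  3 kb tandem gene cassettes at 1% pairwise divergence — the tandem
  duplication structure of V-gene arrays — plus a D/J tail;
- a second haplotype at 2% divergence (IG haplotypes are unusually
  heterozygous), optionally with cassette copy-number change;
- reads of 3 kb ± 0.6 kb (min 500 bp) at 30× per haplotype with 0.2%
  i.i.d. substitution errors, scaled ~5× down from real HiFi length at
  the same depth and error regime;
- injected defects with truth: `deleted_segment` (removed from the
  evaluated assembly while reads still come from the full genome) and
  `inversion` with an N-gap planted at the 5′ breakpoint.

Alignment inside fixtures uses an **exact-placement oracle aligner**:
every read is placed from its recorded origin and the known defect
geometry, with NM/MD computed against the evaluated assembly. Reads whose
origin was deleted are remapped whole to the homologous retained
coordinates — the behaviour a real aligner exhibits when the true origin
is absent — and reads crossing an inversion breakpoint are soft-clipped at
the breakpoint, with the longer side aligned. This keeps fixtures
hermetic, byte-reproducible under a seed, and independent of external
binaries; `minimap2 -ax map-pb` can be substituted for integration runs.

What the fixtures do **not** emulate: homopolymer-context indel errors
(the dominant residual HiFi error mode), chimeric or contaminant reads,
coverage bias, supplementary/split alignments from a real aligner, and
Mb-scale events. Passing tests therefore demonstrate that the detectors
recover the targeted defect signatures under idealized alignment, not
that real-data alignment noise is handled; the MAPQ-0 and clip channels
are exercised only lightly by simulation.

## Numerical and design choices

- Pileup accumulation uses difference arrays + cumulative sums for
  span-shaped tracks and scatter-adds for mismatch positions; the test
  suite pins every column against a naive per-position Python recount.
- Depth at a read's deleted positions counts toward depth by design (see
  above); insertion bases anchor to no reference position.
- Flag/break intervals are maximal runs extracted from boolean masks;
  merging is exact, no smoothing or morphological closing is applied.
- The read-level fast path takes substitutions from MD-derived aligned
  pairs when the tag is present and otherwise walks the CIGAR against the
  contig sequence; both paths are asserted equal on every fixture read.
- Records whose sequence length contradicts their CIGAR are skipped and
  counted (surfaced in the run manifest), never silently dropped.
- Empty inputs degrade deterministically: empty streams give all-zero
  columns, empty cohorts zeroed summaries, empty call tables empty
  summaries.
- Determinism: one seeded `numpy` Generator per simulation stage, sorted
  iteration everywhere, no timestamps in outputs; re-running a fixed
  config is byte-identical, including figures.

## Known limitations

- Break categorization beyond the four reference-context categories
  (e.g. separating repeat-induced from join-induced zero-coverage) is out
  of scope; so are structural-variant calling, consensus polishing and
  assembly-graph analysis — the package localizes and classifies evidence
  for manual or external follow-up.
- The locus-level call floors are calibrated on synthetic conditions; on
  real species they are a starting point, not a validated clinical
  threshold.
- e_r from supplementary alignments is excluded from pileup statistics by
  default (they contribute to clip summaries only), which undercounts
  evidence from split reads at real breakpoints.
- The per-position tables are written uncompressed; for Mb-scale loci
  they reach tens of MB.
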