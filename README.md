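# igqc — assembly-quality assessment of immunoglobulin loci from long reads

Immunoglobulin loci (IGH, IGK, IGL) are repeat-rich, highly heterozygous
regions carrying the V, D and J gene segments that V(D)J recombination
assembles into antibodies. They are among the hardest regions of a
vertebrate genome to assemble correctly, and genome-wide quality metrics
(N50, BUSCO, k-mer completeness) say little about whether an IG locus is
right. Generic single-nucleotide evaluators assume a near-complete diploid
assembly and treat ~50% read error rates as ordinary heterozygosity — the
exact signature of a *missing haplotype segment* in an IG locus.

`igqc` evaluates IG loci directly from HiFi read alignments. It is aimed
at assembly curators and immunogenomics researchers who need to decide,
locus by locus, whether an assembly's IG representation can be trusted.

## The metrics

Let the assembly be G = G₁…G_l and R the aligned reads. For a read r
aligned over n(r) reference-matched positions,

- d(r, G) = Σᵢ 1(rᵢ ≠ gᵢ) — substitutions over aligned columns,
  e_r = d(r, G)/n(r) — its mismatch rate. A read is **poorly aligned**
  when e_r > θ, with θ = 0.01: HiFi error is < 0.5%, so >1% mismatch
  implicates the assembly.
- **Read-oriented view:** for each position j with covering reads J_j,
  E_j = Σ_{x∈J_j} 1(e_x > θ). Position j is **poorly supported** when
  E_j > 5. Clusters of poorly supported positions, together with locally
  elevated coverage, are the signature of sequence missing from the
  assembly — displaced reads pile up on the closest retained homolog.
- **Basepair-oriented view:** δ_j = Σ_{x∈J_j} 1(x_j ≠ G_j) counts reads
  disagreeing at j itself; support = (|J_j| − δ_j)/|J_j|.
- **Coverage breaks:** maximal runs of positions with depth ≤ 2,
  categorized by reference context (N-gap > contig end > zero coverage >
  low coverage). A break coinciding with an N-run marks a suspect
  scaffolding join — the signature of a false inversion.
- **Gene calls:** a gene is read-affected when > 5 poorly aligned reads
  overlap it, and lacks perfect base support unless every position is
  covered with support > 80%.
- Reads with MAPQ 0 (ambiguous placement in repeats or between
  haplotypes) are counted and reported in separate bins, never treated as
  errors by themselves.

Per-locus calls (mismatch / break / good, with mismatch taking precedence)
aggregate across species into a summary table with group percentages.

A seeded synthetic module generates diploid IG-like loci (tandem gene
cassettes, tunable divergence), simulates HiFi-like reads, and injects the
two defect archetypes — a deleted haplotype segment and an inversion with
an N-gap breakpoint — with machine-readable truth, so every detector is
verifiable without any external data or aligner.

## Worked example

Simulate a diploid 100 kb locus whose evaluated assembly is missing a
20 kb segment of the alternate haplotype, align the full-genome reads with
the built-in oracle aligner, and evaluate:

```sh
igqc simulate --outdir sim --seed 7 --locus-length 100000 \
     --defect deletion:hap2:15000:35000
samtools sort -o aln.bam sim/alignments.sam && samtools index aln.bam
igqc evaluate --assembly sim/assembly.fasta --alignments aln.bam \
     --loci sim/loci.bed --genes sim/genes.tsv --outdir out --species demo_wolf
```

The evaluate command prints the locus call:

```
demo_wolf	IGH	mismatch
```

`out/IGH_hap1.flags.tsv` localizes the poorly supported cluster on the
retained haplotype — it covers the 15–35 kb homolog of the deleted
segment (1-based coordinates):

```
contig	start	end	length
hap1	12412	37568	25157
```

and `out/IGH_hap1.genes.tsv` shows exactly the V genes inside that region
losing support, while D/J genes outside it stay clean:

```
gene_id	poor_read_count	read_affected	min_support_pct	base_affected
IGHV1	0	False	96.3	False
IGHV2	18	True	64.7	True
IGHV3	33	True	41.8	True
...
IGHD1	0	False	96.4	False
IGHJ1	0	False	96.3	False
```

`poor_read_count` is the number of reads with e_r > 1% overlapping the
gene; `min_support_pct` the worst per-position base support. The ~47%
support inside the cluster is the haplotype-collapse signature: about half
the covering reads belong to the deleted haplotype. `out/*.png` renders
the MAPQ-stacked coverage track with red (poorly supported) and purple
(coverage break) overlays; every drawn overlay is also listed in
`out/*.overlays.tsv`.

Aggregating many species' calls:

```sh
igqc summarize calls.tsv --out summary.tsv
```

produces per-(locus, resolution) counts, percentages to 0.1%, and
any-error rows.

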