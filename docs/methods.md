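# Methods

## Problem and model

A fast-neutron bombardment (FNB) mutant carries a small number of induced
deletions, one of which causes its phenotype. Jointly genotyping the mutant
against controls turns causality into a genotype-pattern constraint: the
causal deletion is homozygous in the mutant pool and behaves predictably in
every control. fnbfind implements that constraint for three designs:

* **recessive_bsa** — F2 bulked segregants of a recessive mutant. The
  wild-type-like pool is a mixture of homozygous wild-type and heterozygous
  plants, so its pooled genotype at the causal site is called heterozygous;
  the wild-type accession is homozygous reference.
* **nonrecessive_f3** — pools built from F3 families fixed for phenotype;
  the wild-type-like pool is homozygous reference.
* **individual** — no segregating population; the mutant is compared to the
  wild-type control only, so linkage evidence is unavailable and the output
  is a candidate list rather than a mapped locus.

In all designs, every *irrelevant mutant* (an independently derived FNB
line co-genotyped in the same joint calling) must be homozygous reference:
a lesion shared between independent lines is background (natural variation
against the reference, or a caller artifact), not the cause of one line's
phenotype. This cohort condition is evaluated as part of the pattern, after
the core roles, so each exclusion names the exact sample that failed
(stages: QUALITY → PATTERN → COHORT).

Deletion identity is defined on normalized alleles: shared trailing bases
are trimmed, alleles are left-aligned through reference repeats when a
FASTA is supplied, and a variant is a deletion iff the ALT is then a proper
prefix of the REF. The deleted bases exclude the VCF anchor base: a record
at 1-based position p removing L bases deletes the half-open 0-based
interval [p, p+L). All internal arithmetic is half-open 0-based; VCF
(1-based anchored), GFF3 (1-based inclusive) and BED (0-based half-open)
conventions are converted at the boundary. Multiallelic records are
decomposed per ALT, with a sample's genotype for allele *a* set by how many
of its two alleles equal *a*; any missing allele makes the call MISSING.

MISSING genotypes never satisfy an expectation by default. The
`lenient_missing` flag relaxes this for irrelevant-mutant samples only,
where a no-call at a deeply covered site is usually a depth fluctuation in
a sample whose genotype is not load-bearing.

## Consequence calling

Deletions are intersected with an interval-indexed GFF3. Per gene, the
representative transcript is the one with the longest summed CDS (one
consequence per gene; per-transcript calls would multiply rows without
changing the ranking). UTRs use explicit UTR features when present,
otherwise exon-minus-CDS; introns are exon gaps. The effect rule is:

* deletion contains a gene's entire CDS set → whole/partial gene loss;
* otherwise CDS overlap o > 0: frameshift if o mod 3 ≠ 0, in-frame if
  o mod 3 = 0;
* no CDS overlap → non-coding.

`cds_bases_deleted` is the overlap with the union of CDS intervals across
overlapped genes, so it is bounded by the deletion length even when genes
overlap. A deletion touching several region classes is labelled MIXED and
keeps the most severe effect; a deletion spanning two genes reports both
gene ids with one effect each. Classification is strand-invariant by
construction (the same bases are removed either way). Ranking is a stable
sort: gene loss and frameshift above in-frame, above UTR, intronic,
intergenic, ties broken by genomic order.

## PAV detection

Large deletions are detected from windowed mean depth, not from the VCF:
a multi-kilobase loss is not representable as an anchored indel record.
Each track is normalized by its genome-wide median of non-empty window
depths, making calls invariant to total sequencing effort. A window is
depleted when mutant/control normalized depth ≤ `max_mutant_ratio` *and*
control normalized depth ≥ `min_control_norm_depth`. Parameters, with
defaults and rationale:

| parameter | default | why |
|---|---|---|
| `window_size` | 500 bp | resolves deletions ≥ ~1 kb at 20–40x without noise-dominated windows |
| `max_mutant_ratio` | 0.1 | "extremely low" rather than zero: tolerates reads mismapped into a true deletion |
| `min_control_norm_depth` | 0.5 | a region depleted in both samples (repeat, shared deletion) is evidence of nothing |
| `min_windows` | 2 | one depleted window at 30x is within Poisson noise |
| `merge_gap_windows` | 1 | bridges single rescued windows inside long deletions |

Runs of depleted windows are merged gap-tolerantly; a call's zygosity hint
is HOMOZYGOUS_LOSS when mean mutant normalized depth ≤ 0.1, else
PARTIAL_LOSS (a heterozygous loss sits near 0.5). Decreasing
`max_mutant_ratio` can only shrink the flagged set (monotonicity), and
scaling either track's raw depths leaves calls unchanged. Window grids
must be identical across samples; resampling is out of scope, as is
breakpoint refinement from split reads or discordant pairs.

## Segregation test

`chisq_segregation` is the uncorrected chi-square goodness-of-fit with
1 df, expected counts scaled to the observed total; uncorrected because
that is the standard for two-class segregation ratios (a Yates flag
exists). `fits_ratio` is p ≥ α, i.e. failure to reject; a warning fires
when any expected count is below 5. The p-value comes from the chi-square
survival function; tests cross-check it against the independent erfc
identity p = erfc(√(x/2)).

## Quality thresholds

No universal QUAL/GQ/DP cutoffs exist for pooled designs, so the defaults
(site QUAL ≥ 30, per-sample GQ ≥ 20, DP ≥ 5) are conventional hard-filter
values chosen once and exposed in the config; the pipeline presumes ≥ 20x
pooled coverage, where they are loose. A missing QUAL/GQ/DP field fails a
non-zero threshold: an unquantified call should not pass a quality gate.

## Simulator

The simulator emulates the target study structure: a mutant pool, a
wild-type-like pool, a wild-type control and a cohort of irrelevant mutant
lines, jointly genotyped at ~30x (typical pooled WGS depth for this
application; a 20x floor is the practical minimum). Defaults implant one
7 bp causal CDS deletion and 50 background variants (shared deletions,
heterozygous-in-mutant deletions, cohort-private deletions, low-quality
sites, SNVs, insertions — background deletion lengths 1–18 bp, the small-
deletion regime). The genome is uniform-random sequence; gene models are
non-overlapping, 2–3 CDS exons with UTRs. Small deletions are emitted as
left-aligned anchored VCF records; large deletions only depress windowed
depth (homozygous loss keeps a 0.01 residual-mapping ratio, heterozygous
0.5), drawn as Poisson counts on window sums — no read-level simulation,
no sequencing-error model, no real reference genome. Per-sample DP is
Poisson(30), GQ fixed at 99 except where an event is designed to fail the
quality stage.

What passing on this generator shows — and does not. It validates the
filtering logic, the consequence arithmetic and the depth-ratio caller
under clean conditions. It does not model mapping artifacts in repeats,
pooled allele-frequency noise at finite pool sizes (pool genotypes are
emitted as clean 0/1 or 1/1 calls), caller-specific indel representation
quirks, or GC-dependent coverage — so real data can add false candidates
that these tests cannot surface, and the visual/Sanger confirmation step
remains the user's responsibility.

The seed fully determines every output byte (one `numpy` generator,
fixed draw order). Event placement rejects positions within 15 bp of any
other event or feature boundary, which keeps left-alignment from drifting
an implanted deletion across a feature edge.

## Problem sizes

Tests and the acceptance script run on 500 kb single-chromosome fixtures
(~51 variants, 20 genes) for filter/annotation checks, and 1 Mb / 2000
windows × 100 replicates for PAV recovery and specificity — sizes at which
every property asserted is stable across seeds while the whole suite stays
in seconds.

## Known limitations

* Pooled genotypes are treated as categorical calls; no allele-frequency
  modelling, sliding-window linkage statistics, or QTL-seq machinery.
* PAV boundaries are window-quantized (±1 window); no breakpoint assembly.
* The cohort condition assumes irrelevant lines were genotyped jointly;
  with no cohort samples it degrades gracefully to the two/three-sample
  patterns.
* GVCF handling, variant calling and alignment are upstream of this tool.
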