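# fnbfind

Candidate causative deletion finder for **fast-neutron bombardment (FNB)**
plant mutants, built around joint multi-sample whole-genome sequencing.

FNB mutagenesis produces chromosomal deletions from a single base pair to
hundreds of kilobases, typically null alleles. Given a joint-called VCF for
a mutant and its controls, fnbfind identifies the candidate causative
deletion by:

1. **Design-aware genotype-pattern filtering.** A causative deletion must be
   homozygous (`1/1`) in the mutant pool; the other samples pin it down
   according to the experimental design:

   | design | mutant pool | wild-type-like pool | wild-type control | irrelevant mutants |
   |---|---|---|---|---|
   | `recessive_bsa` (F2 bulked segregants) | 1/1 | 0/1 | 0/0 | 0/0 |
   | `nonrecessive_f3` (F3-fixed pools) | 1/1 | 0/0 | 0/0 | 0/0 |
   | `individual` (no population) | 1/1 | — | 0/0 | 0/0 |

   Irrelevant mutants are independently derived FNB lines included in the
   joint calling as mutual controls: any variant they share with the mutant
   is background, not causal. Quality gates (site QUAL, per-sample GQ and
   DP) run first; every exclusion is logged with its stage and failing
   sample.

2. **Consequence annotation.** Surviving deletions are classified against a
   GFF3 annotation (CDS / UTR / intron / intergenic). A CDS deletion whose
   length L satisfies L mod 3 ≠ 0 is a **frameshift** — the strongest
   null-allele candidate; L mod 3 = 0 is an in-frame deletion; a deletion
   swallowing a gene's whole CDS is a gene loss. Candidates are ranked by
   severity.

3. **Presence–absence (PAV) detection.** Deletions too large for an indel
   caller are found from windowed read depth: windows where the mutant's
   median-normalized depth falls to ≤ 0.1 of the control's, while the
   control itself stays covered, are merged into PAV calls. Regions
   depleted in *both* samples are deliberately excluded.

4. **Segregation testing.** A chi-square goodness-of-fit test of observed
   mutant : wild-type-like F2 counts against 1:3 (statistic
   χ² = Σ(Oᵢ−Eᵢ)²/Eᵢ, 1 df) decides whether the mutant is a single
   recessive locus, and hence which filtering design applies.

A bundled simulator generates complete synthetic experiments — genome,
annotation, implanted deletions, multi-sample VCF, depth tracks — with a
truth set, so the whole pipeline is testable without sequencing data.

## Worked example

Simulate a recessive bulked-segregant experiment (one 7 bp causal CDS
deletion, 50 background variants, one 5 kb homozygous large deletion) and
run the pipeline on it:

```sh
fnbfind simulate --seed 7 -o sim --large-deletion 5000
fnbfind run -c config.yaml     # config pointing at sim/ (see examples/)
```

prints

```
stage counts: {'QUALITY': 3, 'PATTERN': 22, 'COHORT': 5, 'PASSED': 1, 'NON_DELETION': 20}
#1 chr1:97888-97895 7 bp FRAMESHIFT gene0019
PAV chr1:346000-351000 (5000 bp, HOMOZYGOUS_LOSS)
```

Of 51 variant records, 3 failed quality gates, 22 violated the expected
genotype pattern (e.g. present in the wild-type control), 5 were shared
with an irrelevant mutant line, and 20 were SNVs/insertions (side channel).
The single survivor is the implanted 7 bp CDS deletion, ranked first as a
frameshift in `gene0019`; the depth channel independently recovers the 5 kb
deletion as a homozygous loss. Output files (`candidates.vcf`,
`candidates.tsv`, `decisions.tsv`, `pav_calls.bed`) land in `output_dir`.

The segregation test that selects the design:

```sh
$ fnbfind segtest --mutant 14 --wildtype-like 46 --ratio 1:3
observed 14 mutant : 46 wild-type-like, expected 15:45 under 1:3
chi-square = 0.0889 (df=1), p = 0.7656
segregation fits 1:3 at alpha = 0.05
```

14 of 60 F2 plants showing the mutant phenotype is consistent with a single
recessive locus, so the `recessive_bsa` design applies.

A commented configuration template, including conventional upstream
alignment/calling parameters, is in `examples/config_template.yaml`.

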