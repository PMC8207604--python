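# fnbfind pipeline configuration template.
#
# Copy, fill in the paths and sample names from your joint-called VCF, and
# run:  fnbfind run -c config.yaml
#
# ---------------------------------------------------------------------------
# Upstream variant calling (NOT executed by fnbfind).
# fnbfind consumes a joint multi-sample VCF.  A conventional upstream recipe
# for pooled FNB whole-genome sequencing is BWA-MEM alignment (min seed
# length 19, band width 100, off-diagonal X-dropoff 100) followed by GATK4
# HaplotypeCaller in GVCF mode per sample and joint genotyping of the whole
# cohort, with:
#   --assembly-region-padding 100
#   --base-quality-score-threshold 19
#   --max-reads-per-alignment-start 50
#   --max-assembly-region-size 300
#   --min-assembly-region-size 50
# Select indels from the joint calls before handing the VCF to fnbfind.
# Aim for at least 20x depth per pool; ~30x is comfortable.
# ---------------------------------------------------------------------------

vcf: cohort.joint.indels.vcf.gz      # joint multi-sample VCF (gzip ok)
gff3: annotation.gff3                # gene annotation (gzip ok)
reference: genome.fa                 # optional; enables indel left-alignment

# recessive_bsa   - F2 bulked segregants, mutant recessive (needs all 3 pools)
# nonrecessive_f3 - F3-fixed pools, wild-type-like pool homozygous wild type
# individual      - no segregating population: mutant vs wild-type control
design: recessive_bsa

samples:
  mutant_pool: wn_mut            # pooled mutant-phenotype plants
  wildtype_like_pool: wn_wtl     # pooled wild-type-like segregants (omit for `individual`)
  wildtype_control: A17          # wild-type accession
  irrelevant_mutants: [fnb12, fnb31]   # other FNB lines in the joint calling

thresholds:            # all overridable; defaults shown
  min_site_qual: 30
  min_genotype_quality: 20
  min_depth: 5

lenient_missing: false  # true tolerates ./. in irrelevant mutants only

pav:                   # optional: windowed depth comparison for large deletions
  mutant_depth: depth_mut.bed     # chrom<TAB>start<TAB>end<TAB>mean_depth
  control_depth: depth_A17.bed
  params:
    window_size: 500
    max_mutant_ratio: 0.1         # mutant/control normalized-depth ceiling
    min_control_norm_depth: 0.5   # control must itself be covered
    min_windows: 2
    merge_gap_windows: 1

output_dir: fnbfind_out
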