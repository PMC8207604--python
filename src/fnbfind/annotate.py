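"""Consequence annotation of candidate deletions against a GFF3 annotation.

A deletion that survives genotype filtering is prioritized by where it
lands: a coding-sequence hit whose length is not a multiple of three shifts
the reading frame and is the strongest candidate for a null allele; UTR,
intronic and intergenic deletions rank below it.  Deletions that swallow a
gene's entire coding sequence are whole-gene losses, the hallmark lesion of
fast-neutron mutagenesis.

All intervals are handled half-open 0-based internally; GFF3 input is
1-based inclusive and converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .variant_model import Variant, VariantClass

__all__ = [
    "RegionClass",
    "Effect",
    "GeneModel",
    "Transcript",
    "FeatureIndex",
    "ConsequenceCall",
    "load_annotation",
    "classify_deletion",
    "prioritize",
]

log = logging.getLogger(__name__)


class RegionClass(str, Enum):
    INTERGENIC = "INTERGENIC"
    INTRONIC = "INTRONIC"
    UTR = "UTR"
    CDS = "CDS"
    MIXED = "MIXED"


class Effect(str, Enum):
    NONCODING = "NONCODING"
    IN_FRAME_DELETION = "IN_FRAME_DELETION"
    FRAMESHIFT = "FRAMESHIFT"
    WHOLE_OR_PARTIAL_GENE_LOSS = "WHOLE_OR_PARTIAL_GENE_LOSS"


# smaller rank = more severe; whole-gene loss sorts with/above frameshift
_SEVERITY: dict[Effect | RegionClass, int] = {
    Effect.WHOLE_OR_PARTIAL_GENE_LOSS: 0,
    Effect.FRAMESHIFT: 1,
    Effect.IN_FRAME_DELETION: 2,
    RegionClass.UTR: 3,
    RegionClass.INTRONIC: 4,
    RegionClass.INTERGENIC: 5,
}


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(i for i in intervals if i[1] > i[0]):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap(a: tuple[int, int], intervals: Sequence[tuple[int, int]]) -> int:
    return sum(max(0, min(a[1], e) - max(a[0], s)) for s, e in intervals)


def _subtract(span: tuple[int, int], holes: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """``span`` minus the union of ``holes`` (all half-open)."""
    out: list[tuple[int, int]] = []
    cur = span[0]
    for s, e in _merge(holes):
        if s > cur:
            out.append((cur, min(s, span[1])))
        cur = max(cur, e)
        if cur >= span[1]:
            break
    if cur < span[1]:
        out.append((cur, span[1]))
    return [(s, e) for s, e in out if e > s]


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    cds: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int]] = field(default_factory=list)  # explicit UTR features

    @property
    def total_cds(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GeneModel:
    """One gene with its transcripts; consequence calls use the
    representative transcript (longest total CDS)."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]  # 0-based half-open
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def representative(self) -> Transcript | None:
        coding = [t for t in self.transcripts if t.cds]
        if coding:
            return max(coding, key=lambda t: (t.total_cds, t.transcript_id))
        return max(self.transcripts, key=lambda t: t.transcript_id) if self.transcripts else None

    def region_intervals(self) -> dict[RegionClass, list[tuple[int, int]]]:
        """CDS / UTR / intron intervals of the representative transcript.

        UTRs fall back to exonic-minus-CDS when no explicit UTR features
        exist; introns are the within-span gaps between exons.
        """
        t = self.representative
        if t is None:
            return {RegionClass.CDS: [], RegionClass.UTR: [], RegionClass.INTRONIC: [(self.span[0], self.span[1])]}
        exons = _merge(t.exons) or [self.span]
        cds = _merge(t.cds)
        if t.utrs:
            utr = _merge(t.utrs)
        else:
            utr = [iv for ex in exons for iv in _subtract(ex, cds)]
        introns = _subtract((exons[0][0], exons[-1][1]), exons)
        return {RegionClass.CDS: cds, RegionClass.UTR: utr, RegionClass.INTRONIC: introns}


class FeatureIndex:
    """Interval-indexed gene models supporting point and range queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.genes[g.gene_id] = g
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            if g.span[1] > g.span[0]:
                tree.addi(g.span[0], g.span[1], g.gene_id)

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    def query(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span overlaps half-open ``[start, end)``, by position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.overlap(start, max(end, start + 1))]
        return sorted(hits, key=lambda g: (g.span, g.gene_id))


_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "5'UTR", "3'UTR", "UTR"}


def load_annotation(path: str | Path) -> FeatureIndex:
    """Load a GFF3 file (gzip accepted) into a :class:`FeatureIndex`.

    Requires gene/mRNA/exon/CDS features; UTR features are optional.  An
    mRNA without CDS children is retained but treated as non-coding (logged
    as a warning).  Introns are implied by exon gaps, not read.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gm = GeneModel(
            gene_id=g.id,
            chrom=g.seqid,
            strand=g.strand,
            span=(g.start - 1, g.end),
        )
        for mrna in db.children(g, featuretype=("mRNA", "transcript")):
            t = Transcript(transcript_id=mrna.id)
            for f in db.children(mrna):
                iv = (f.start - 1, f.end)
                if f.featuretype == "exon":
                    t.exons.append(iv)
                elif f.featuretype == "CDS":
                    t.cds.append(iv)
                elif f.featuretype in _UTR_TYPES:
                    t.utrs.append(iv)
            if not t.cds:
                log.warning("mRNA %s of gene %s has no CDS; treated as non-coding", mrna.id, g.id)
            gm.transcripts.append(t)
        genes.append(gm)
    return FeatureIndex(genes)


@dataclass
class ConsequenceCall:
    """Genomic context and coding consequence of one deletion."""

    variant: Variant
    region_class: RegionClass
    effect: Effect
    gene_ids: list[str] = field(default_factory=list)
    cds_bases_deleted: int = 0
    gene_effects: dict[str, Effect] = field(default_factory=dict)

    @property
    def severity(self) -> int:
        if self.effect is not Effect.NONCODING:
            return _SEVERITY[self.effect]
        if self.region_class in (RegionClass.UTR, RegionClass.INTRONIC, RegionClass.INTERGENIC):
            return _SEVERITY[self.region_class]
        # noncoding MIXED: rank by the most severe touched region
        return _SEVERITY[RegionClass.UTR]


def classify_deletion(v: Variant, idx: FeatureIndex) -> ConsequenceCall:
    """Classify one deletion's genomic context and coding effect.

    The deleted interval excludes the VCF anchor base.  Region classes
    touched by the interval are collected with precedence
    CDS > UTR > intron > intergenic; more than one class yields MIXED while
    keeping the most severe effect.  ``cds_bases_deleted`` is the overlap
    with the union of representative-transcript CDS intervals of all
    overlapped genes, so it never exceeds the deletion length.  A deletion
    containing a gene's entire CDS set is a whole/partial gene loss;
    otherwise a CDS overlap not divisible by three is a frameshift, one
    divisible by three an in-frame deletion.  Strand never matters: a
    deletion removes the same coding bases either way.
    """
    if v.variant_class is not VariantClass.DELETION:
        raise ValueError("classify_deletion expects a DELETION variant")
    dele = v.deleted_interval
    if v.chrom not in idx.chroms:
        log.warning("chromosome %s absent from annotation; classifying as intergenic", v.chrom)
        return ConsequenceCall(v, RegionClass.INTERGENIC, Effect.NONCODING)

    genes = idx.query(v.chrom, *dele)
    touched: set[RegionClass] = set()
    all_cds: list[tuple[int, int]] = []
    gene_ids: list[str] = []
    gene_effects: dict[str, Effect] = {}
    whole_loss = False

    for g in genes:
        gene_ids.append(g.gene_id)
        regions = g.region_intervals()
        g_cds = _overlap(dele, regions[RegionClass.CDS])
        if g_cds > 0:
            touched.add(RegionClass.CDS)
            all_cds.extend(regions[RegionClass.CDS])
        if _overlap(dele, regions[RegionClass.UTR]) > 0:
            touched.add(RegionClass.UTR)
        if _overlap(dele, regions[RegionClass.INTRONIC]) > 0:
            touched.add(RegionClass.INTRONIC)
        cds_set = regions[RegionClass.CDS]
        g_whole = bool(cds_set) and all(dele[0] <= s and e <= dele[1] for s, e in cds_set)
        if g_whole:
            whole_loss = True
            gene_effects[g.gene_id] = Effect.WHOLE_OR_PARTIAL_GENE_LOSS
        elif g_cds > 0:
            gene_effects[g.gene_id] = (
                Effect.FRAMESHIFT if g_cds % 3 else Effect.IN_FRAME_DELETION
            )
        else:
            gene_effects[g.gene_id] = Effect.NONCODING

    # any deleted base outside every gene span is intergenic territory
    span_union = _merge([g.span for g in genes])
    if _overlap(dele, span_union) < dele[1] - dele[0]:
        touched.add(RegionClass.INTERGENIC)

    cds_bases = _overlap(dele, _merge(all_cds))
    if whole_loss:
        effect = Effect.WHOLE_OR_PARTIAL_GENE_LOSS
    elif cds_bases > 0:
        effect = Effect.FRAMESHIFT if cds_bases % 3 else Effect.IN_FRAME_DELETION
    else:
        effect = Effect.NONCODING

    if not touched:
        region = RegionClass.INTERGENIC
    elif len(touched) == 1:
        region = next(iter(touched))
    else:
        region = RegionClass.MIXED
    return ConsequenceCall(v, region, effect, gene_ids, cds_bases, gene_effects)


def prioritize(calls: list[ConsequenceCall]) -> list[ConsequenceCall]:
    """Stable severity sort: gene loss / frameshift first, then in-frame,
    UTR, intronic, intergenic; ties broken by genomic order."""
    return sorted(
        calls,
        key=lambda c: (c.severity, c.variant.chrom, c.variant.pos, c.variant.alt_allele),
    )
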