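"""Variant data model and VCF I/O.

Fast-neutron bombardment (FNB) induces chromosomal deletions from a single
base pair up to hundreds of kilobases.  The small end of that spectrum is
visible to a joint variant caller as indel polymorphisms between the mutant
and its controls; this module holds the in-memory representation of those
records and the readers/writers the pipeline uses.

Conventions
-----------
* VCF positions are 1-based with an anchor base shared by REF and ALT; the
  bases actually removed by a deletion therefore occupy the 1-based inclusive
  interval ``[pos+1, pos+deletion_length]``.
* Internally every interval is half-open 0-based; :attr:`Variant.deleted_interval`
  returns the deleted bases in that convention, ``(pos, pos+deletion_length)``.
* Multiallelic records are decomposed into one biallelic :class:`Variant` per
  ALT allele, with genotypes re-mapped per allele.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GTClass",
    "VariantClass",
    "DesignMode",
    "GenotypeCall",
    "Variant",
    "SampleRoles",
    "StudyDesign",
    "QualityThresholds",
    "classify_genotype",
    "is_deletion",
    "normalize_indel",
    "read_vcf",
    "write_vcf",
]


class GTClass(str, Enum):
    """Diploid genotype classes as they appear in the filtering logic."""

    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"
    OTHER = "OTHER"


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "INSERTION"
    DELETION = "DELETION"
    MNV_OR_COMPLEX = "MNV_OR_COMPLEX"


class DesignMode(str, Enum):
    """Experimental scenario that fixes the expected genotype pattern.

    RECESSIVE_BSA
        F2 bulked-segregant design for a recessive mutant: mutant pool,
        wild-type-like pool (mixture of heterozygous and homozygous
        wild-type segregants), and a wild-type control accession.
    NONRECESSIVE_F3
        Non-recessive mutant; pools built from F3 families fixed for
        phenotype, so the wild-type-like pool is homozygous wild type.
    INDIVIDUAL
        No segregating population: the mutant itself versus a wild-type
        control.
    """

    RECESSIVE_BSA = "RECESSIVE_BSA"
    NONRECESSIVE_F3 = "NONRECESSIVE_F3"
    INDIVIDUAL = "INDIVIDUAL"


def classify_genotype(gt_string: str) -> GTClass:
    """Map a raw VCF GT string to a :class:`GTClass`.

    ``0/0`` is homozygous wild type, ``0/1`` (or ``1/0``) heterozygous and
    ``1/1`` homozygous mutant; ``./.`` or ``.`` is a no-call.  Phased ``|``
    separators behave exactly like ``/``.  Any allele index above 1, haploid
    or polyploid calls, or unparseable strings map to ``OTHER`` — total over
    all inputs, never raises.
    """
    if not isinstance(gt_string, str) or not gt_string:
        return GTClass.OTHER
    alleles = gt_string.replace("|", "/").split("/")
    if alleles == ["."]:
        return GTClass.MISSING
    if len(alleles) != 2:
        return GTClass.OTHER
    if "." in alleles:
        return GTClass.MISSING if alleles == [".", "."] else GTClass.OTHER
    try:
        a, b = int(alleles[0]), int(alleles[1])
    except ValueError:
        return GTClass.OTHER
    if a < 0 or b < 0 or a > 1 or b > 1:
        return GTClass.OTHER
    n_alt = a + b
    return (GTClass.HOM_REF, GTClass.HET, GTClass.HOM_ALT)[n_alt]


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site."""

    sample_id: str
    gt_class: GTClass
    genotype_quality: int | None = None  # GQ, phred-scaled
    depth: int | None = None  # DP, reads
    raw_gt: str = "."


@dataclass
class Variant:
    """One decomposed (biallelic) VCF record.

    ``pos`` is the 1-based anchored VCF position; for deletions the anchor
    base is shared by REF and ALT and is *not* part of the deleted interval.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float | None
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    variant_class: VariantClass = VariantClass.MNV_OR_COMPLEX

    def __post_init__(self) -> None:
        if self.variant_class == VariantClass.MNV_OR_COMPLEX:
            self.variant_class = _classify_alleles(self.ref_allele, self.alt_allele)

    @property
    def deletion_length(self) -> int:
        """Number of deleted bases (0 for non-deletions)."""
        if self.variant_class is not VariantClass.DELETION:
            return 0
        return len(self.ref_allele) - len(self.alt_allele)

    @property
    def deleted_interval(self) -> tuple[int, int]:
        """Deleted bases as a half-open 0-based interval, anchor excluded.

        A deletion at 1-based anchor ``pos`` removing ``L`` bases deletes the
        1-based inclusive span ``[pos+1, pos+L]``, i.e. 0-based ``[pos, pos+L)``.
        """
        if self.variant_class is not VariantClass.DELETION:
            raise ValueError("deleted_interval is defined for deletions only")
        return self.pos, self.pos + self.deletion_length

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def _classify_alleles(ref: str, alt: str) -> VariantClass:
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(ref) > len(alt) >= 1 and ref.startswith(alt):
        return VariantClass.DELETION
    if len(alt) > len(ref) >= 1 and alt.startswith(ref):
        return VariantClass.INSERTION
    return VariantClass.MNV_OR_COMPLEX


def normalize_indel(
    pos: int, ref: str, alt: str, chrom_seq: str | None = None
) -> tuple[int, str, str]:
    """Normalize an allele pair: trim shared bases and left-align.

    Shared trailing bases are trimmed (extending leftwards through the
    reference when one allele would become empty, if ``chrom_seq`` is given),
    then shared leading bases beyond the single anchor are trimmed.  This is
    the standard parsimony/left-alignment procedure for indels; without a
    reference sequence only in-record trimming is performed.

    ``chrom_seq`` is the full chromosome sequence (0-based indexable);
    ``pos`` is 1-based.  Returns ``(pos, ref, alt)`` normalized.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                if chrom_seq is None or pos <= 1:
                    break
                pos -= 1
                prev = chrom_seq[pos - 1].upper()
                ref, alt = prev + ref, prev + alt
            ref, alt = ref[:-1], alt[:-1]
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def is_deletion(v: Variant) -> bool:
    """True iff the variant removes reference bases (anchored deletion)."""
    return v.variant_class is VariantClass.DELETION


@dataclass(frozen=True)
class SampleRoles:
    """Maps experimental roles to VCF sample names.

    ``irrelevant_mutants`` are independently derived FNB lines included in
    the joint calling as mutual controls; a true causative deletion is
    private to one line, so these samples must all be homozygous wild type
    at a candidate site.
    """

    mutant_pool: str
    wildtype_control: str
    wildtype_like_pool: str | None = None
    irrelevant_mutants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = self.all_samples()
        if len(set(ids)) != len(ids):
            raise ValueError(f"sample roles must be distinct, got {ids}")

    def all_samples(self) -> tuple[str, ...]:
        out = [self.mutant_pool]
        if self.wildtype_like_pool is not None:
            out.append(self.wildtype_like_pool)
        out.append(self.wildtype_control)
        out.extend(self.irrelevant_mutants)
        return tuple(out)


@dataclass(frozen=True)
class StudyDesign:
    mode: DesignMode

    def validate_roles(self, roles: SampleRoles) -> None:
        """Raise ``ValueError`` if the roles are incomplete for this design."""
        needs_wtl = self.mode in (DesignMode.RECESSIVE_BSA, DesignMode.NONRECESSIVE_F3)
        if needs_wtl and roles.wildtype_like_pool is None:
            raise ValueError(
                f"design {self.mode.value} requires a wildtype_like_pool sample"
            )


@dataclass(frozen=True)
class QualityThresholds:
    """Site- and genotype-level quality gates applied before pattern matching.

    Defaults (QUAL >= 30, per-sample GQ >= 20 and DP >= 5) are explicit,
    conventional hard-filter values and are user-overridable; the pipeline
    assumes >= 20x pooled sequencing so DP 5 is a loose floor.
    """

    min_site_qual: float = 30.0
    min_genotype_quality: int = 20
    min_depth: int = 5

    def __post_init__(self) -> None:
        if min(self.min_site_qual, self.min_genotype_quality, self.min_depth) < 0:
            raise ValueError("quality thresholds must be non-negative")


def _decompose_genotype(
    alleles: Sequence[int], alt_index: int
) -> GTClass:
    """Genotype of one sample for one decomposed ALT allele.

    HOM_ALT iff both alleles equal the target allele, HET iff exactly one,
    HOM_REF iff none and no allele is missing; any missing allele yields
    MISSING.  Non-diploid calls map to OTHER.
    """
    if len(alleles) != 2:
        return GTClass.OTHER
    if any(a is None or a < 0 for a in alleles):
        return GTClass.MISSING
    n = sum(1 for a in alleles if a == alt_index)
    return (GTClass.HOM_REF, GTClass.HET, GTClass.HOM_ALT)[n]


def read_vcf(
    path: str | Path,
    roles: "SampleRoles | Sequence[str]",
    reference: str | Path | None = None,
) -> Iterator[Variant]:
    """Stream :class:`Variant` objects from a (possibly gzipped) VCF.

    Multiallelic records are decomposed into one Variant per ALT with
    genotypes re-mapped per allele.  GT, GQ and DP are extracted for every
    role sample (``roles`` may also be a plain list of sample names).  If
    ``reference`` (FASTA) is given, indel alleles are left-aligned against
    it before classification.

    Raises ``ValueError`` if a role sample is missing from the VCF header.
    """
    from cyvcf2 import VCF

    wanted = list(roles.all_samples() if isinstance(roles, SampleRoles) else roles)
    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    missing = [s for s in wanted if s not in header_samples]
    if missing:
        raise ValueError(
            f"role sample(s) {missing} not found in VCF header of {path} "
            f"(header has {header_samples})"
        )
    sample_idx = {s: header_samples.index(s) for s in wanted}

    ref_fasta = None
    if reference is not None:
        from pyfaidx import Fasta

        ref_fasta = Fasta(str(reference), as_raw=True)

    for rec in vcf:
        gts = rec.genotypes  # [[a1, a2, phased], ...]
        gqs = rec.format("GQ")
        dps = rec.format("DP")
        if gqs is not None:
            gqs = gqs.reshape(len(header_samples), -1)[:, 0]
        if dps is not None:
            dps = dps.reshape(len(header_samples), -1)[:, 0]
        for ai, alt in enumerate(rec.ALT, start=1):
            pos, ref_allele, alt_allele = rec.POS, rec.REF, alt
            if ref_fasta is not None and rec.CHROM in ref_fasta.keys():
                seq = str(ref_fasta[rec.CHROM][:])
                pos, ref_allele, alt_allele = normalize_indel(
                    pos, ref_allele, alt_allele, seq
                )
            else:
                pos, ref_allele, alt_allele = normalize_indel(
                    pos, ref_allele, alt_allele
                )
            calls: dict[str, GenotypeCall] = {}
            for sample, si in sample_idx.items():
                raw = gts[si]
                allele_pair = raw[:-1]  # last element is the phased flag
                gt_class = _decompose_genotype(allele_pair, ai)
                gq = int(gqs[si]) if gqs is not None and gqs[si] >= 0 else None
                dp = int(dps[si]) if dps is not None and dps[si] >= 0 else None
                sep = "|" if raw[-1] else "/"
                raw_gt = sep.join("." if a < 0 else str(a) for a in allele_pair)
                calls[sample] = GenotypeCall(sample, gt_class, gq, dp, raw_gt)
            yield Variant(
                chrom=rec.CHROM,
                pos=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                qual=rec.QUAL,
                calls=calls,
            )


_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">',
]

_GT_STRING = {
    GTClass.HOM_REF: "0/0",
    GTClass.HET: "0/1",
    GTClass.HOM_ALT: "1/1",
    GTClass.MISSING: "./.",
    GTClass.OTHER: "./.",
}


def write_vcf(
    path: str | Path,
    variants: Iterable[Variant],
    samples: Sequence[str],
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write biallelic Variants to a VCF v4.2 text file (gzip if ``.gz``).

    Genotypes are emitted from the classed calls (``0/0``, ``0/1``, ``1/1``,
    ``./.``); raw GT strings are used where available so phasing survives a
    round trip.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in variants:
            qual = "." if v.qual is None else f"{v.qual:g}"
            cols = [v.chrom, str(v.pos), ".", v.ref_allele, v.alt_allele, qual, ".", ".", "GT:GQ:DP"]
            for s in samples:
                call = v.calls.get(s)
                if call is None:
                    cols.append("./.:.:.")
                    continue
                gt = call.raw_gt if call.raw_gt != "." else _GT_STRING[call.gt_class]
                gq = "." if call.genotype_quality is None else str(call.genotype_quality)
                dp = "." if call.depth is None else str(call.depth)
                cols.append(f"{gt}:{gq}:{dp}")
            fh.write("\t".join(cols) + "\n")
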