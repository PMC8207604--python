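"""Synthetic FNB experiments with a known truth set.

Generates everything a pipeline run needs — a random genome, gene models,
implanted deletions, a joint multi-sample VCF, and windowed depth tracks —
together with a machine-readable record of every implanted event and its
expected fate in the filter cascade.  Small deletions (and background SNVs,
insertions and shared variants) appear as anchored VCF records; large
deletions appear only as coverage dropouts in the depth tracks, mirroring
the two detection channels of the pipeline.

Defaults emulate the study structure this tool targets: ~30x pooled
sequencing of a mutant pool, a wild-type-like pool, a wild-type control and
a small cohort of irrelevant mutant lines, with one causal coding deletion
of a few base pairs against a few dozen background variants.  Depth is
simulated at window level (Poisson counts on window sums), not read level,
which keeps a full experiment in well under a second.

The seed fully determines every output byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotate import Effect, RegionClass
from .pav_detect import DepthTrack, PavCall
from .variant_model import (
    DesignMode,
    GenotypeCall,
    GTClass,
    SampleRoles,
    StudyDesign,
    Variant,
    normalize_indel,
    write_vcf,
)

__all__ = [
    "DeletionSpec",
    "LargeDeletionSpec",
    "SimConfig",
    "TruthEvent",
    "SimResult",
    "simulate_experiment",
    "evaluate_against_truth",
]

_BASES = np.array(list("ACGT"))
_MARGIN = 15  # bp kept clear around implanted events (left-shift safety)


@dataclass(frozen=True)
class DeletionSpec:
    """A small implanted deletion: target feature class and length in bp."""

    target: str = "CDS"  # CDS | UTR | intron | intergenic
    length: int = 7

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("deletion length must be >= 1")
        if self.target not in ("CDS", "UTR", "intron", "intergenic"):
            raise ValueError(f"unknown target class {self.target!r}")


@dataclass(frozen=True)
class LargeDeletionSpec:
    """A large deletion visible only as a coverage dropout."""

    length: int = 5000
    zygosity: str = "hom"  # hom | het
    shared: bool = False  # also absent in the control (never a candidate)


@dataclass
class SimConfig:
    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (("chr1", 500_000),)
    n_genes: int = 20
    design: DesignMode = DesignMode.RECESSIVE_BSA
    n_irrelevant: int = 2
    causal: tuple[DeletionSpec, ...] = (DeletionSpec("CDS", 7),)
    # background event counts by kind; total 50 by default
    background: Mapping[str, int] = field(
        default_factory=lambda: {
            "shared_deletion": 12,
            "het_in_mutant_deletion": 10,
            "cohort_hom_deletion": 5,
            "low_quality_deletion": 3,
            "snv": 12,
            "insertion": 8,
        }
    )
    large_deletions: tuple[LargeDeletionSpec, ...] = ()
    mean_depth: float = 30.0
    window_size: int = 500
    residual_ratio: float = 0.01  # mismapping floor inside homozygous losses

    def roles(self) -> SampleRoles:
        wtl = "wtl_pool" if self.design is not DesignMode.INDIVIDUAL else None
        return SampleRoles(
            mutant_pool="mut_pool",
            wildtype_like_pool=wtl,
            wildtype_control="A17",
            irrelevant_mutants=tuple(f"irr{i+1}" for i in range(self.n_irrelevant)),
        )

    def study_design(self) -> StudyDesign:
        return StudyDesign(self.design)

    def validate(self) -> None:
        if self.background.get("cohort_hom_deletion", 0) > 0 and self.n_irrelevant == 0:
            raise ValueError("cohort_hom_deletion events need at least one irrelevant mutant")
        for spec in self.causal:
            if spec.length < 1:
                raise ValueError("causal deletion length must be >= 1")


@dataclass
class TruthEvent:
    kind: str  # causal | shared_deletion | ... | large_deletion
    chrom: str
    pos: int  # 1-based VCF anchor (small events) / 0-based start (large)
    end: int  # 0-based half-open end of the removed bases
    length: int
    target: str
    ref: str = ""
    alt: str = ""
    genotypes: dict[str, str] = field(default_factory=dict)
    expected_stage: str = "PASS"  # PASS | QUALITY | PATTERN | COHORT | NON_DELETION
    expected_region: str | None = None
    expected_effect: str | None = None
    zygosity: str | None = None  # large deletions
    shared: bool = False

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utrs: list[tuple[int, int, str]]  # (start, end, five|three)


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    genes: list[_Gene]
    variants: list[Variant]
    tracks: dict[str, DepthTrack]  # sample -> track (mutant pool and control)
    truth: list[TruthEvent]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA, GFF3, VCF, depth BEDs and truth JSON; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "annotation.gff3",
            "vcf": outdir / "variants.vcf",
            "truth": outdir / "truth.json",
        }
        _write_fasta(self.genome, paths["fasta"])
        _write_gff3(self.genes, paths["gff3"])
        roles = self.config.roles()
        contigs = {c: len(s) for c, s in self.genome.items()}
        write_vcf(paths["vcf"], self.variants, roles.all_samples(), contigs)
        from .pav_detect import write_depth_bed

        for sample, track in self.tracks.items():
            p = outdir / f"depth_{sample}.bed"
            write_depth_bed(track, p)
            paths[f"depth_{sample}"] = p
        with open(paths["truth"], "w") as fh:
            json.dump([asdict(t) for t in self.truth], fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _write_fasta(genome: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _write_gff3(genes: Sequence[_Gene], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            a = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{a}\n"
            )
            mid = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.exon{i};Parent={mid}\n"
                )
            phase = 0
            cds_order = g.cds if g.strand == "+" else list(reversed(g.cds))
            phased = []
            for s, e in cds_order:
                phased.append((s, e, phase))
                phase = (3 - ((e - s) - phase) % 3) % 3
            for i, (s, e, ph) in enumerate(sorted(phased), 1):
                fh.write(
                    f"{g.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{ph}\t"
                    f"ID={mid}.cds{i};Parent={mid}\n"
                )
            for i, (s, e, which) in enumerate(g.utrs, 1):
                ftype = "five_prime_UTR" if which == "five" else "three_prime_UTR"
                fh.write(
                    f"{g.chrom}\tsim\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.utr{i};Parent={mid}\n"
                )


def _make_gene(rng: np.random.Generator, chrom: str, start: int, idx: int) -> _Gene:
    """One gene: UTR'd first/last exons, 2-3 CDS exons, introns between."""
    utr5 = int(rng.integers(60, 120))
    utr3 = int(rng.integers(60, 120))
    n_cds = int(rng.integers(2, 4))
    cds_lens = [int(rng.integers(150, 300)) // 3 * 3 + 1 for _ in range(n_cds)]
    cds_lens[-1] += (3 - sum(cds_lens) % 3) % 3  # total CDS a codon multiple
    intron_lens = [int(rng.integers(100, 250)) for _ in range(n_cds - 1)]

    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    utrs: list[tuple[int, int, str]] = []
    cur = start
    for i, clen in enumerate(cds_lens):
        ex_start = cur
        if i == 0:
            utrs.append((cur, cur + utr5, "five"))
            cur += utr5
        cds.append((cur, cur + clen))
        cur += clen
        if i == n_cds - 1:
            utrs.append((cur, cur + utr3, "three"))
            cur += utr3
        exons.append((ex_start, cur))
        if i < n_cds - 1:
            cur += intron_lens[i]
    strand = "+" if rng.random() < 0.5 else "-"
    return _Gene(f"gene{idx:04d}", chrom, strand, start, cur, exons, cds, utrs)


class _Placer:
    """Tracks occupied intervals so implanted events never collide."""

    def __init__(self) -> None:
        self.used: dict[str, list[tuple[int, int]]] = {}

    def reserve(self, chrom: str, start: int, end: int) -> bool:
        ivs = self.used.setdefault(chrom, [])
        lo, hi = start - _MARGIN, end + _MARGIN
        if any(s < hi and lo < e for s, e in ivs):
            return False
        ivs.append((lo, hi))
        return True


def _region_pool(genes: Sequence[_Gene], genome: Mapping[str, str], target: str) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    if target == "CDS":
        for g in genes:
            out += [(g.chrom, s, e) for s, e in g.cds]
    elif target == "UTR":
        for g in genes:
            out += [(g.chrom, s, e) for s, e, _ in g.utrs]
    elif target == "intron":
        for g in genes:
            bounds = sorted(g.exons)
            for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
                if s2 > e1:
                    out.append((g.chrom, e1, s2))
    elif target == "intergenic":
        by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for chrom, spans in by_chrom.items():
            cur = 1000  # keep clear of the chromosome start
            for s, e in sorted(spans):
                if s > cur:
                    out.append((chrom, cur, s))
                cur = max(cur, e)
            clen = len(genome[chrom])
            if clen - 1000 > cur:
                out.append((chrom, cur, clen - 1000))
    return out


def _place_event(
    rng: np.random.Generator,
    pool: list[tuple[str, int, int]],
    length: int,
    placer: _Placer,
    what: str,
) -> tuple[str, int]:
    """Pick a (chrom, 0-based start) for an event wholly inside one region."""
    need = length + 2 * _MARGIN
    eligible = [r for r in pool if r[2] - r[1] >= need]
    if not eligible:
        raise RuntimeError(f"no {what} region can hold an event of {length} bp")
    for _ in range(200):
        chrom, rs, re_ = eligible[int(rng.integers(len(eligible)))]
        start = int(rng.integers(rs + _MARGIN, re_ - length - _MARGIN + 1))
        if placer.reserve(chrom, start, start + length):
            return chrom, start
    raise RuntimeError(f"could not place a {length} bp event in {what} after 200 tries")


def _genotypes_for(kind: str, cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    roles = cfg.roles()
    gts = {s: "0/0" for s in roles.all_samples()}
    causal_wtl = "0/1" if cfg.design is DesignMode.RECESSIVE_BSA else "0/0"
    if kind in ("causal", "snv", "insertion", "low_quality_deletion"):
        gts[roles.mutant_pool] = "1/1"
        if roles.wildtype_like_pool:
            gts[roles.wildtype_like_pool] = causal_wtl
    elif kind == "shared_deletion":
        gts = {s: "1/1" for s in roles.all_samples()}
    elif kind == "het_in_mutant_deletion":
        gts[roles.mutant_pool] = "0/1"
        if roles.wildtype_like_pool:
            gts[roles.wildtype_like_pool] = "0/1"
    elif kind == "cohort_hom_deletion":
        gts[roles.mutant_pool] = "1/1"
        if roles.wildtype_like_pool:
            gts[roles.wildtype_like_pool] = causal_wtl
        victim = roles.irrelevant_mutants[int(rng.integers(len(roles.irrelevant_mutants)))]
        gts[victim] = "1/1"
    else:
        raise ValueError(f"unknown event kind {kind}")
    return gts


_EXPECTED_STAGE = {
    "causal": "PASS",
    "shared_deletion": "PATTERN",
    "het_in_mutant_deletion": "PATTERN",
    "cohort_hom_deletion": "COHORT",
    "low_quality_deletion": "QUALITY",
    "snv": "NON_DELETION",
    "insertion": "NON_DELETION",
}

_TARGET_REGION = {
    "CDS": RegionClass.CDS,
    "UTR": RegionClass.UTR,
    "intron": RegionClass.INTRONIC,
    "intergenic": RegionClass.INTERGENIC,
}


def _gt_to_class(gt: str) -> GTClass:
    from .variant_model import classify_genotype

    return classify_genotype(gt)


def simulate_experiment(cfg: SimConfig) -> SimResult:
    """Build a complete synthetic experiment from ``cfg`` (seed-determined).

    Small events become left-aligned anchored VCF records with per-sample
    GT/GQ/DP and a site QUAL; large deletions only depress the mutant's
    (and, if shared, the control's) windowed depth.  The truth set records
    every event with its expected filter stage, region class and effect.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {
        name: lut[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        for name, length in cfg.genome
    }

    # --- gene models ---------------------------------------------------
    total_len = sum(l for _, l in cfg.genome)
    genes: list[_Gene] = []
    gi = 0
    for chrom, clen in cfg.genome:
        share = max(1, round(cfg.n_genes * clen / total_len)) if cfg.n_genes else 0
        cursor = 2000
        for _ in range(share):
            if gi >= cfg.n_genes:
                break
            cursor += int(rng.integers(2000, 6000))
            g = _make_gene(rng, chrom, cursor, gi)
            if g.end > clen - 2000:
                break
            genes.append(g)
            cursor = g.end
            gi += 1

    placer = _Placer()
    pools = {t: _region_pool(genes, genome, t) for t in ("CDS", "UTR", "intron", "intergenic")}
    roles = cfg.roles()
    samples = roles.all_samples()

    variants: list[Variant] = []
    truth: list[TruthEvent] = []

    def emit_small(kind: str, target: str, length: int, vclass: str) -> None:
        chrom, start = _place_event(rng, pools[target], max(length, 1), placer, target)
        seq = genome[chrom]
        if vclass == "deletion":
            pos = start  # 1-based anchor == 0-based deleted start
            ref = seq[pos - 1 : pos + length]
            alt = seq[pos - 1]
            pos, ref, alt = normalize_indel(pos, ref, alt, seq)
        elif vclass == "snv":
            ref = seq[start]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            pos = start + 1
        else:  # insertion
            ins = "".join(rng.choice(_BASES, size=length))
            pos = start + 1
            ref = seq[start]
            alt = ref + ins
            pos, ref, alt = normalize_indel(pos, ref, alt, seq)
        gts = _genotypes_for(kind, cfg, rng)
        qual = 10.0 if kind == "low_quality_deletion" else float(rng.uniform(300, 2000))
        calls = {}
        for s in samples:
            dp = int(rng.poisson(cfg.mean_depth))
            calls[s] = GenotypeCall(s, _gt_to_class(gts[s]), 99, max(dp, 6), gts[s])
        variants.append(Variant(chrom, pos, ref, alt, qual, calls))
        expected_region = expected_effect = None
        if kind == "causal":
            expected_region = _TARGET_REGION[target].value
            if target == "CDS":
                expected_effect = (
                    Effect.FRAMESHIFT if length % 3 else Effect.IN_FRAME_DELETION
                ).value
            else:
                expected_effect = Effect.NONCODING.value
        truth.append(
            TruthEvent(
                kind=kind,
                chrom=chrom,
                pos=pos,
                end=pos + (length if vclass == "deletion" else 0),
                length=length,
                target=target,
                ref=ref,
                alt=alt,
                genotypes=gts,
                expected_stage=_EXPECTED_STAGE[kind],
                expected_region=expected_region,
                expected_effect=expected_effect,
            )
        )

    for spec in cfg.causal:
        emit_small("causal", spec.target, spec.length, "deletion")
    bg_targets = ("intergenic", "intron", "UTR")
    for kind, count in cfg.background.items():
        for _ in range(count):
            target = bg_targets[int(rng.integers(len(bg_targets)))]
            if kind == "snv":
                emit_small(kind, target, 1, "snv")
            elif kind == "insertion":
                emit_small(kind, target, int(rng.integers(1, 6)), "insertion")
            else:
                emit_small(kind, target, int(rng.integers(1, 19)), "deletion")

    variants.sort(key=lambda v: (v.chrom, v.pos, v.alt_allele))

    # --- large deletions & depth tracks --------------------------------
    large_spans: list[tuple[LargeDeletionSpec, str, int, int]] = []
    for spec in cfg.large_deletions:
        chrom, start = _place_event(
            rng, pools["intergenic"], spec.length, placer, "intergenic"
        )
        large_spans.append((spec, chrom, start, start + spec.length))
        truth.append(
            TruthEvent(
                kind="large_deletion",
                chrom=chrom,
                pos=start,
                end=start + spec.length,
                length=spec.length,
                target="intergenic",
                expected_stage="PAV" if not spec.shared else "NO_CALL",
                zygosity=spec.zygosity,
                shared=spec.shared,
            )
        )

    def make_track(sample: str, affected: bool) -> DepthTrack:
        windows: dict[str, np.ndarray] = {}
        for chrom, clen in cfg.genome:
            starts = np.arange(0, clen, cfg.window_size)
            ends = np.minimum(starts + cfg.window_size, clen)
            lam = cfg.mean_depth * (ends - starts).astype(float)
            for spec, dchrom, ds, de in large_spans:
                if dchrom != chrom or (not affected and not spec.shared):
                    continue
                ratio = cfg.residual_ratio if spec.zygosity == "hom" else 0.5
                ov = np.maximum(
                    0, np.minimum(ends, de) - np.maximum(starts, ds)
                ).astype(float)
                frac = ov / (ends - starts)
                lam = lam * (1 - frac * (1 - ratio))
            counts = rng.poisson(lam)
            depth = counts / (ends - starts)
            windows[chrom] = np.column_stack([starts, ends, depth]).astype(float)
        return DepthTrack(sample, cfg.window_size, windows)

    tracks = {
        roles.mutant_pool: make_track(roles.mutant_pool, affected=True),
        roles.wildtype_control: make_track(roles.wildtype_control, affected=False),
    }
    return SimResult(cfg, genome, genes, variants, tracks, truth)


def evaluate_against_truth(
    passed: Sequence[Variant],
    truth: Sequence[TruthEvent],
    pav_calls: Sequence[PavCall] | None = None,
    window_size: int | None = None,
) -> dict[str, float]:
    """Event-level precision/recall of candidates and PAV boundary error.

    Candidates match truth on (chrom, pos, ref, alt).  For PAV calls, each
    expected (non-shared, mutant) large deletion is matched to the best
    overlapping call and the boundary error is the larger of the start and
    end offsets, in windows.
    """
    expected = {t.key() for t in truth if t.expected_stage == "PASS"}
    got = {v.key() for v in passed}
    tp = len(expected & got)
    metrics: dict[str, float] = {
        "n_expected": float(len(expected)),
        "n_reported": float(len(got)),
        "precision": tp / len(got) if got else (1.0 if not expected else 0.0),
        "recall": tp / len(expected) if expected else 1.0,
    }
    if pav_calls is not None:
        want = [t for t in truth if t.kind == "large_deletion" and t.expected_stage == "PAV"]
        w = float(window_size or 1)
        errors: list[float] = []
        hit = 0
        for t in want:
            overl = [
                c for c in pav_calls
                if c.chrom == t.chrom and c.start < t.end and t.pos < c.end
            ]
            if not overl:
                continue
            best = max(overl, key=lambda c: min(c.end, t.end) - max(c.start, t.pos))
            errors.append(max(abs(best.start - t.pos), abs(best.end - t.end)) / w)
            hit += 1
        metrics["pav_n_expected"] = float(len(want))
        metrics["pav_n_calls"] = float(len(pav_calls))
        metrics["pav_recall"] = hit / len(want) if want else 1.0
        metrics["pav_max_boundary_error_windows"] = max(errors) if errors else 0.0
    return metrics
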