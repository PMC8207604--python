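"""Pipeline orchestration and the merged candidate report.

``run_pipeline`` wires the stages together — quality and genotype-pattern
filtering of the joint VCF, deletion selection, consequence annotation and
prioritization, plus depth-based PAV calling when tracks are supplied — and
writes a filtered VCF, a TSV candidate report, a TSV decision log and a BED
of PAV calls.  All outputs are deterministically ordered so a rerun over
the same inputs is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .annotate import ConsequenceCall, classify_deletion, load_annotation, prioritize
from .genotype_filter import FilterResult, filter_candidates
from .pav_detect import (
    PavCall,
    PavParams,
    detect_pav,
    read_depth_bed,
    write_pav_bed,
)
from .variant_model import (
    DesignMode,
    QualityThresholds,
    SampleRoles,
    StudyDesign,
    read_vcf,
    write_vcf,
)

__all__ = ["PipelineConfig", "CandidateReport", "load_config", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: Path
    gff3: Path | None
    design: StudyDesign
    roles: SampleRoles
    thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    reference: Path | None = None
    lenient_missing: bool = False
    mutant_depth: Path | None = None
    control_depth: Path | None = None
    pav_params: PavParams = field(default_factory=PavParams)
    output_dir: Path = Path("fnbfind_out")


def load_config(path: str | Path, overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    """Parse the YAML pipeline config; ``overrides`` (e.g. CLI flags) win.

    Validates role completeness for the chosen design before any I/O.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides or {})
    try:
        design = StudyDesign(DesignMode(str(raw["design"]).upper()))
    except KeyError:
        raise ValueError("config error: 'design' is required") from None
    s = raw.get("samples", {})
    try:
        roles = SampleRoles(
            mutant_pool=s["mutant_pool"],
            wildtype_control=s["wildtype_control"],
            wildtype_like_pool=s.get("wildtype_like_pool"),
            irrelevant_mutants=tuple(s.get("irrelevant_mutants", ())),
        )
    except KeyError as e:
        raise ValueError(f"config error: samples.{e.args[0]} is required") from None
    design.validate_roles(roles)
    t = raw.get("thresholds", {})
    thresholds = QualityThresholds(
        min_site_qual=float(t.get("min_site_qual", 30)),
        min_genotype_quality=int(t.get("min_genotype_quality", 20)),
        min_depth=int(t.get("min_depth", 5)),
    )
    pav = raw.get("pav", {}) or {}
    pav_params = PavParams(**{k: v for k, v in (pav.get("params") or {}).items()})
    for key in ("vcf",):
        if key not in raw:
            raise ValueError(f"config error: '{key}' is required")
    return PipelineConfig(
        vcf=Path(raw["vcf"]),
        gff3=Path(raw["gff3"]) if raw.get("gff3") else None,
        design=design,
        roles=roles,
        thresholds=thresholds,
        reference=Path(raw["reference"]) if raw.get("reference") else None,
        lenient_missing=bool(raw.get("lenient_missing", False)),
        mutant_depth=Path(pav["mutant_depth"]) if pav.get("mutant_depth") else None,
        control_depth=Path(pav["control_depth"]) if pav.get("control_depth") else None,
        pav_params=pav_params,
        output_dir=Path(raw.get("output_dir", "fnbfind_out")),
    )


@dataclass
class CandidateReport:
    """Everything a rerun needs to audit: ranked candidates with their
    consequence, PAV calls, per-stage exclusion counts, and the exact
    design/parameters used."""

    candidates: list[ConsequenceCall]
    pav_calls: list[PavCall]
    filter_result: FilterResult
    design: StudyDesign
    roles: SampleRoles
    thresholds: QualityThresholds
    version: str = __version__

    @property
    def stage_counts(self) -> dict[str, int]:
        return self.filter_result.stage_counts()

    def candidate_rows(self) -> list[dict[str, Any]]:
        rows = []
        for c in self.candidates:
            v = c.variant
            s, e = v.deleted_interval
            rows.append(
                {
                    "chrom": v.chrom,
                    "start": s,
                    "end": e,
                    "length": v.deletion_length,
                    "ref": v.ref_allele,
                    "alt": v.alt_allele,
                    "region_class": c.region_class.value,
                    "effect": c.effect.value,
                    "gene_ids": ",".join(c.gene_ids) or ".",
                    "cds_bases_deleted": c.cds_bases_deleted,
                }
            )
        return rows


def _write_decisions_tsv(result: FilterResult, roles: SampleRoles, path: Path) -> None:
    cols = ["chrom", "pos", "ref", "alt"] + list(roles.all_samples()) + [
        "stage",
        "failing_sample",
        "passed",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for d in sorted(result.decisions, key=lambda d: d.variant.key()):
            v = d.variant
            row = [v.chrom, str(v.pos), v.ref_allele, v.alt_allele]
            row += [d.observed.get(s, "MISSING") for s in roles.all_samples()]
            row += [d.failed_stage.value, d.failing_sample or ".", str(d.passed).lower()]
            fh.write("\t".join(str(x) for x in row) + "\n")


def _write_candidates_tsv(report: CandidateReport, path: Path) -> None:
    cols = [
        "rank", "chrom", "start", "end", "length", "ref", "alt",
        "region_class", "effect", "gene_ids", "cds_bases_deleted",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, row in enumerate(report.candidate_rows(), 1):
            fh.write("\t".join(str(x) for x in ([i] + list(row.values()))) + "\n")


def run_pipeline(config: PipelineConfig | str | Path) -> CandidateReport:
    """Execute the full cascade and write all outputs under ``output_dir``.

    Stage errors propagate with the stage name; partially written outputs
    are removed on failure.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    cfg = config
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        try:
            variants = list(read_vcf(cfg.vcf, cfg.roles, reference=cfg.reference))
        except Exception as e:
            raise RuntimeError(f"[stage: read_vcf] {e}") from e
        log.info("read %d decomposed variant records from %s", len(variants), cfg.vcf)

        try:
            result = filter_candidates(
                variants, cfg.design, cfg.roles, cfg.thresholds,
                lenient_missing=cfg.lenient_missing,
            )
        except Exception as e:
            raise RuntimeError(f"[stage: genotype_filter] {e}") from e
        for stage, n in result.stage_counts().items():
            log.info("filter stage %s: %d", stage, n)

        calls: list[ConsequenceCall]
        if cfg.gff3 is not None:
            try:
                idx = load_annotation(cfg.gff3)
                calls = prioritize([classify_deletion(v, idx) for v in result.passed])
            except Exception as e:
                raise RuntimeError(f"[stage: annotate] {e}") from e
        else:
            from .annotate import Effect, RegionClass

            calls = [
                ConsequenceCall(v, RegionClass.INTERGENIC, Effect.NONCODING)
                for v in result.passed
            ]

        pav_calls: list[PavCall] = []
        if cfg.mutant_depth and cfg.control_depth:
            try:
                mut = read_depth_bed(cfg.mutant_depth)
                ctl = read_depth_bed(cfg.control_depth)
                pav_calls = detect_pav(mut, ctl, cfg.pav_params)
            except Exception as e:
                raise RuntimeError(f"[stage: pav_detect] {e}") from e
            log.info("pav_detect: %d calls", len(pav_calls))
            if cfg.gff3 is not None:
                idx = load_annotation(cfg.gff3)
                for c in pav_calls:
                    genes = idx.query(c.chrom, c.start, c.end)
                    if genes:
                        log.info(
                            "PAV %s:%d-%d overlaps gene(s) %s",
                            c.chrom, c.start, c.end, ",".join(g.gene_id for g in genes),
                        )

        report = CandidateReport(
            candidates=calls,
            pav_calls=pav_calls,
            filter_result=result,
            design=cfg.design,
            roles=cfg.roles,
            thresholds=cfg.thresholds,
        )

        p = outdir / "candidates.vcf"
        written.append(p)
        write_vcf(p, result.passed, cfg.roles.all_samples())
        p = outdir / "candidates.tsv"
        written.append(p)
        _write_candidates_tsv(report, p)
        p = outdir / "decisions.tsv"
        written.append(p)
        _write_decisions_tsv(result, cfg.roles, p)
        if pav_calls or (cfg.mutant_depth and cfg.control_depth):
            p = outdir / "pav_calls.bed"
            written.append(p)
            write_pav_bed(pav_calls, p)
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
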