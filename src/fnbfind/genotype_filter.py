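"""Design-aware genotype-pattern filtering with cohort background subtraction.

The causative deletion of an FNB mutant must be homozygous in the mutant
pool, and every control sample constrains it further: in a recessive
bulked-segregant design the wild-type-like pool (a mix of heterozygous and
homozygous wild-type segregants) is expected heterozygous at the causal
site, while the wild-type accession and every irrelevant mutant line in the
joint calling must be homozygous wild type.  A variant shared with any
control is background, not a candidate.

Stages run quality -> pattern (role pools) -> cohort (irrelevant mutants),
and every exclusion is recorded with the stage and the sample that failed,
so the filtering cascade is fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .variant_model import (
    DesignMode,
    GTClass,
    QualityThresholds,
    SampleRoles,
    StudyDesign,
    Variant,
    VariantClass,
    is_deletion,
)

__all__ = [
    "FilterStage",
    "ExpectedPattern",
    "FilterDecision",
    "FilterResult",
    "expected_pattern",
    "quality_filter",
    "matches_pattern",
    "filter_candidates",
]


class FilterStage(str, Enum):
    QUALITY = "QUALITY"
    PATTERN = "PATTERN"
    COHORT = "COHORT"
    NONE = "NONE"


@dataclass(frozen=True)
class ExpectedPattern:
    """Expected genotype class per role; a pure function of the design mode."""

    mutant_pool: GTClass
    wildtype_control: GTClass
    wildtype_like_pool: GTClass | None
    irrelevant_mutants: GTClass

    def as_dict(self, roles: SampleRoles) -> dict[str, GTClass]:
        out = {roles.mutant_pool: self.mutant_pool, roles.wildtype_control: self.wildtype_control}
        if self.wildtype_like_pool is not None and roles.wildtype_like_pool is not None:
            out[roles.wildtype_like_pool] = self.wildtype_like_pool
        for s in roles.irrelevant_mutants:
            out[s] = self.irrelevant_mutants
        return out


def expected_pattern(design: StudyDesign) -> ExpectedPattern:
    """Genotype pattern a causative deletion must show under ``design``.

    The mutant pool is always homozygous mutant (1/1) and wild-type control
    and irrelevant mutants always homozygous wild type (0/0); the
    wild-type-like pool is heterozygous (0/1) for a recessive BSA design,
    homozygous wild type for F3-fixed non-recessive pools, and absent for an
    individual mutant.
    """
    wtl = {
        DesignMode.RECESSIVE_BSA: GTClass.HET,
        DesignMode.NONRECESSIVE_F3: GTClass.HOM_REF,
        DesignMode.INDIVIDUAL: None,
    }[design.mode]
    return ExpectedPattern(
        mutant_pool=GTClass.HOM_ALT,
        wildtype_control=GTClass.HOM_REF,
        wildtype_like_pool=wtl,
        irrelevant_mutants=GTClass.HOM_REF,
    )


@dataclass
class FilterDecision:
    """Provenance of one variant's trip through the filter cascade."""

    variant: Variant
    passed: bool
    failed_stage: FilterStage
    observed: dict[str, GTClass] = field(default_factory=dict)
    failing_sample: str | None = None

    def __post_init__(self) -> None:
        assert self.passed == (self.failed_stage is FilterStage.NONE)


def quality_filter(v: Variant, t: QualityThresholds, roles: SampleRoles) -> bool:
    """True iff site QUAL and every role sample's GQ and DP meet thresholds.

    A missing QUAL, GQ or DP field counts as failing its threshold (unless
    that threshold is 0): the pipeline presupposes deeply sequenced,
    confidently genotyped sites.
    """
    if v.qual is None:
        if t.min_site_qual > 0:
            return False
    elif v.qual < t.min_site_qual:
        return False
    for sample in roles.all_samples():
        call = v.calls.get(sample)
        if call is None:
            return False
        gq = call.genotype_quality
        dp = call.depth
        if (gq if gq is not None else -1) < t.min_genotype_quality and t.min_genotype_quality > 0:
            return False
        if (dp if dp is not None else -1) < t.min_depth and t.min_depth > 0:
            return False
    return True


def matches_pattern(
    v: Variant,
    design: StudyDesign,
    roles: SampleRoles,
    lenient_missing: bool = False,
) -> FilterDecision:
    """Check a variant's genotypes against the design's expected pattern.

    Role pools (mutant, wild-type-like, control) are checked first and a
    mismatch is a PATTERN failure; the irrelevant-mutant cohort condition is
    checked afterwards and a mismatch there is a COHORT failure, naming the
    offending sample.  A MISSING genotype never matches an expectation
    (strict mode); with ``lenient_missing`` a no-call is tolerated in
    irrelevant-mutant samples only.
    """
    design.validate_roles(roles)
    pattern = expected_pattern(design)
    observed = {s: v.calls[s].gt_class for s in roles.all_samples() if s in v.calls}

    core: list[tuple[str, GTClass]] = [(roles.mutant_pool, pattern.mutant_pool)]
    if pattern.wildtype_like_pool is not None and roles.wildtype_like_pool is not None:
        core.append((roles.wildtype_like_pool, pattern.wildtype_like_pool))
    core.append((roles.wildtype_control, pattern.wildtype_control))

    for sample, want in core:
        got = observed.get(sample, GTClass.MISSING)
        if got is not want:
            return FilterDecision(v, False, FilterStage.PATTERN, observed, sample)
    for sample in roles.irrelevant_mutants:
        got = observed.get(sample, GTClass.MISSING)
        if got is GTClass.MISSING and lenient_missing:
            continue
        if got is not GTClass.HOM_REF:
            return FilterDecision(v, False, FilterStage.COHORT, observed, sample)
    return FilterDecision(v, True, FilterStage.NONE, observed)


@dataclass
class FilterResult:
    """Outcome of :func:`filter_candidates` over a variant stream."""

    passed: list[Variant]
    decisions: list[FilterDecision]
    non_deletions: list[Variant]

    def stage_counts(self) -> dict[str, int]:
        counts = {s.value: 0 for s in FilterStage if s is not FilterStage.NONE}
        counts["PASSED"] = len(self.passed)
        counts["NON_DELETION"] = len(self.non_deletions)
        for d in self.decisions:
            if not d.passed:
                counts[d.failed_stage.value] += 1
        return counts


def filter_candidates(
    variants: Iterable[Variant],
    design: StudyDesign,
    roles: SampleRoles,
    thresholds: QualityThresholds | None = None,
    lenient_missing: bool = False,
) -> FilterResult:
    """Run the full cascade: quality, deletion selection, pattern, cohort.

    Only DELETION-class variants are eligible candidates; SNVs, insertions
    and complex substitutions that survive the quality gate are reported in
    the ``non_deletions`` side channel, never as candidates.  The passed
    list is returned in genomic order and every excluded deletion carries a
    :class:`FilterDecision` naming its failing stage.
    """
    design.validate_roles(roles)
    t = thresholds or QualityThresholds()
    passed: list[Variant] = []
    decisions: list[FilterDecision] = []
    side: list[Variant] = []
    for v in variants:
        if not quality_filter(v, t, roles):
            if is_deletion(v):
                observed = {s: v.calls[s].gt_class for s in roles.all_samples() if s in v.calls}
                decisions.append(FilterDecision(v, False, FilterStage.QUALITY, observed))
            else:
                side.append(v)
            continue
        if not is_deletion(v):
            side.append(v)
            continue
        d = matches_pattern(v, design, roles, lenient_missing=lenient_missing)
        decisions.append(d)
        if d.passed:
            passed.append(v)
    passed.sort(key=lambda v: (v.chrom, v.pos, v.ref_allele, v.alt_allele))
    return FilterResult(passed, decisions, side)
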