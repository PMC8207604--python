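"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions, not from the package's
code paths: plain string genotype comparison, direct interval arithmetic,
and closed-form statistics.
"""

from __future__ import annotations

import math


def oracle_gt_class(gt: str) -> str:
    g = gt.replace("|", "/")
    if g in ("0/0",):
        return "HOM_REF"
    if g in ("0/1", "1/0"):
        return "HET"
    if g == "1/1":
        return "HOM_ALT"
    if g in ("./.", "."):
        return "MISSING"
    return "OTHER"


def oracle_passes(variant, design_mode: str, roles, thresholds, lenient=False) -> bool:
    """Direct conjunction of every filter condition, from raw GT strings."""
    # deletion: ref strictly longer, alt a prefix of ref
    if not (
        len(variant.ref_allele) > len(variant.alt_allele) >= 1
        and variant.ref_allele.startswith(variant.alt_allele)
    ):
        return False
    if variant.qual is None or variant.qual < thresholds.min_site_qual:
        return False
    for s in roles.all_samples():
        c = variant.calls.get(s)
        if c is None:
            return False
        if c.genotype_quality is None or c.genotype_quality < thresholds.min_genotype_quality:
            return False
        if c.depth is None or c.depth < thresholds.min_depth:
            return False
    want = {
        roles.mutant_pool: "HOM_ALT",
        roles.wildtype_control: "HOM_REF",
    }
    if design_mode == "RECESSIVE_BSA":
        want[roles.wildtype_like_pool] = "HET"
    elif design_mode == "NONRECESSIVE_F3":
        want[roles.wildtype_like_pool] = "HOM_REF"
    for s, w in want.items():
        if oracle_gt_class(variant.calls[s].raw_gt) != w:
            return False
    for s in roles.irrelevant_mutants:
        got = oracle_gt_class(variant.calls[s].raw_gt)
        if got == "MISSING" and lenient:
            continue
        if got != "HOM_REF":
            return False
    return True


def oracle_cds_overlap(del_start: int, del_end: int, cds: list[tuple[int, int]]) -> int:
    """Per-base scan of deleted positions against CDS intervals (half-open)."""
    n = 0
    for p in range(del_start, del_end):
        if any(s <= p < e for s, e in cds):
            n += 1
    return n


def oracle_chi2_sf_df1(x: float) -> float:
    """Upper tail of chi-square with 1 df via the erfc identity."""
    return math.erfc(math.sqrt(x / 2.0))


def oracle_decomposed_gt(pair: tuple[int, int] | None, alt_index: int) -> str:
    """Expected genotype class of a diploid call for one decomposed ALT."""
    if pair is None or any(a < 0 for a in pair):
        return "MISSING"
    n = sum(1 for a in pair if a == alt_index)
    return {0: "HOM_REF", 1: "HET", 2: "HOM_ALT"}[n]
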