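"""Expected-pattern logic, quality gating and the full filter cascade."""

from __future__ import annotations

import itertools
import random

import pytest

from fnbfind import (
    DesignMode,
    FilterStage,
    GTClass,
    QualityThresholds,
    SampleRoles,
    StudyDesign,
    expected_pattern,
    filter_candidates,
    matches_pattern,
    quality_filter,
)
from fnbfind.simulator import SimConfig, simulate_experiment
from tests._oracles import oracle_passes
from tests.conftest import make_variant


GTS_PASS_BSA = {"mut_pool": "1/1", "wtl_pool": "0/1", "A17": "0/0",
                "irr1": "0/0", "irr2": "0/0"}


class TestExpectedPattern:
    def test_recessive_bsa(self):
        p = expected_pattern(StudyDesign(DesignMode.RECESSIVE_BSA))
        assert (p.mutant_pool, p.wildtype_like_pool, p.wildtype_control,
                p.irrelevant_mutants) == (
            GTClass.HOM_ALT, GTClass.HET, GTClass.HOM_REF, GTClass.HOM_REF)

    def test_nonrecessive_f3(self):
        p = expected_pattern(StudyDesign(DesignMode.NONRECESSIVE_F3))
        assert p.mutant_pool is GTClass.HOM_ALT
        assert p.wildtype_like_pool is GTClass.HOM_REF
        assert p.wildtype_control is GTClass.HOM_REF

    def test_individual(self):
        p = expected_pattern(StudyDesign(DesignMode.INDIVIDUAL))
        assert p.wildtype_like_pool is None
        assert p.mutant_pool is GTClass.HOM_ALT
        assert p.irrelevant_mutants is GTClass.HOM_REF


class TestQualityFilter:
    def test_good_site_passes(self, roles_bsa):
        v = make_variant(qual=100.0, genotypes=GTS_PASS_BSA, gq=99, dp=30)
        assert quality_filter(v, QualityThresholds(), roles_bsa)

    def test_low_site_qual_fails(self, roles_bsa):
        v = make_variant(qual=10.0, genotypes=GTS_PASS_BSA)
        assert not quality_filter(v, QualityThresholds(), roles_bsa)

    def test_boundary_enumeration_matches_brute_force(self, roles_bsa):
        """All combinations of QUAL/GQ/DP around the default thresholds
        agree with an independently coded predicate."""
        t = QualityThresholds()  # 30 / 20 / 5
        for qual, gq, dp in itertools.product(
            (29.0, 30.0, 31.0, 100.0), (19, 20, 21, 99), (2, 4, 5, 6, 30)
        ):
            v = make_variant(qual=qual, genotypes=GTS_PASS_BSA, gq=gq, dp=dp)
            expected = (qual >= 30) and (gq >= 20) and (dp >= 5)
            assert quality_filter(v, t, roles_bsa) == expected, (qual, gq, dp)

    def test_one_bad_sample_fails(self, roles_bsa):
        gts = dict(GTS_PASS_BSA)
        gts["mut_pool"] = ("1/1", 99, 2)  # DP below the default floor of 5
        v = make_variant(qual=100.0, genotypes=gts)
        assert not quality_filter(v, QualityThresholds(), roles_bsa)


class TestMatchesPattern:
    def test_causal_site_passes(self, roles_bsa, design_bsa):
        """Mutant pool homozygous, wild-type-like heterozygous, control and
        cohort wild type: the recessive causal pattern."""
        v = make_variant(genotypes=GTS_PASS_BSA)
        d = matches_pattern(v, design_bsa, roles_bsa)
        assert d.passed and d.failed_stage is FilterStage.NONE

    def test_shared_with_control_fails_pattern(self):
        """A deletion homozygous in mutant AND control is background, not a
        candidate (individual-mutant design)."""
        roles = SampleRoles(mutant_pool="yl1", wildtype_control="A17")
        v = make_variant(genotypes={"yl1": "1/1", "A17": "1/1"})
        d = matches_pattern(v, StudyDesign(DesignMode.INDIVIDUAL), roles)
        assert not d.passed
        assert d.failed_stage is FilterStage.PATTERN
        assert d.failing_sample == "A17"

    def test_het_in_mutant_fails_pattern(self, roles_bsa, design_bsa):
        gts = dict(GTS_PASS_BSA, mut_pool="0/1")
        d = matches_pattern(make_variant(genotypes=gts), design_bsa, roles_bsa)
        assert d.failed_stage is FilterStage.PATTERN
        assert d.failing_sample == "mut_pool"

    def test_hom_alt_in_irrelevant_fails_cohort(self, roles_bsa, design_bsa):
        gts = dict(GTS_PASS_BSA, irr2="1/1")
        d = matches_pattern(make_variant(genotypes=gts), design_bsa, roles_bsa)
        assert d.failed_stage is FilterStage.COHORT
        assert d.failing_sample == "irr2"

    def test_missing_rejected_strict_allowed_lenient(self, roles_bsa, design_bsa):
        gts = dict(GTS_PASS_BSA, irr1="./.")
        v = make_variant(genotypes=gts)
        assert matches_pattern(v, design_bsa, roles_bsa).failed_stage is FilterStage.COHORT
        assert matches_pattern(v, design_bsa, roles_bsa, lenient_missing=True).passed
        # lenience never extends to core roles
        gts = dict(GTS_PASS_BSA, wtl_pool="./.")
        v = make_variant(genotypes=gts)
        assert not matches_pattern(v, design_bsa, roles_bsa, lenient_missing=True).passed

    def test_design_requires_wtl_pool(self):
        roles = SampleRoles(mutant_pool="m", wildtype_control="c")
        with pytest.raises(ValueError, match="wildtype_like_pool"):
            matches_pattern(
                make_variant(genotypes={"m": "1/1", "c": "0/0"}),
                StudyDesign(DesignMode.RECESSIVE_BSA),
                roles,
            )


def _mixed_fixture(roles):
    """3 deletions carrying the causal pattern + 7 background variants."""
    ok = lambda **kw: dict(GTS_PASS_BSA, **kw)
    passing = [
        make_variant(pos=100, ref="ATG", alt="A", genotypes=GTS_PASS_BSA),
        make_variant(pos=500, ref="GT", alt="G", genotypes=GTS_PASS_BSA),
        make_variant(pos=900, ref="TGCAGCAA", alt="T", genotypes=GTS_PASS_BSA),
    ]
    background = [
        make_variant(pos=150, ref="AT", alt="A", genotypes=ok(A17="1/1")),     # shared
        make_variant(pos=250, ref="CT", alt="C", genotypes=ok(mut_pool="0/1")),  # het mutant
        make_variant(pos=350, ref="GA", alt="G", genotypes=ok(irr1="1/1")),    # cohort
        make_variant(pos=450, ref="A", alt="T", genotypes=GTS_PASS_BSA),       # SNV
        make_variant(pos=550, ref="C", alt="CTT", genotypes=GTS_PASS_BSA),     # insertion
        make_variant(pos=650, ref="TA", alt="T", qual=5.0, genotypes=GTS_PASS_BSA),  # low qual
        make_variant(pos=750, ref="GC", alt="G", genotypes=ok(wtl_pool="1/1")),  # wrong wtl
    ]
    return passing, background


def test_filter_candidates_mixed_fixture(roles_bsa, design_bsa):
    passing, background = _mixed_fixture(roles_bsa)
    result = filter_candidates(background + passing, design_bsa, roles_bsa)
    assert [v.pos for v in result.passed] == [100, 500, 900]
    counts = result.stage_counts()
    assert counts == {
        "QUALITY": 1, "PATTERN": 3, "COHORT": 1, "PASSED": 3, "NON_DELETION": 2,
    }
    # stage-count conservation over the whole input
    assert sum(counts.values()) == len(passing) + len(background)
    passed_keys = {v.key() for v in result.passed}
    for d in result.decisions:
        assert d.passed == (d.variant.key() in passed_keys)


def test_filter_is_order_independent(roles_bsa, design_bsa):
    passing, background = _mixed_fixture(roles_bsa)
    variants = passing + background
    rnd = random.Random(7)
    baseline = None
    for _ in range(5):
        rnd.shuffle(variants)
        got = {v.key() for v in filter_candidates(variants, design_bsa, roles_bsa).passed}
        baseline = baseline if baseline is not None else got
        assert got == baseline


def test_empty_stream_gives_empty_result(roles_bsa, design_bsa):
    result = filter_candidates([], design_bsa, roles_bsa)
    assert result.passed == [] and result.decisions == []


@pytest.mark.parametrize("design_mode", list(DesignMode))
@pytest.mark.parametrize("seed", [3, 17])
def test_oracle_equivalence_on_simulated_fixtures(design_mode, seed):
    """The passed set equals an independently coded brute-force evaluation
    of the full conjunction of conditions, for every design."""
    cfg = SimConfig(seed=seed, design=design_mode)
    sim = simulate_experiment(cfg)
    roles, design = cfg.roles(), cfg.study_design()
    t = QualityThresholds()
    result = filter_candidates(sim.variants, design, roles, t)
    expected = {
        v.key() for v in sim.variants
        if oracle_passes(v, design_mode.value, roles, t)
    }
    assert {v.key() for v in result.passed} == expected
    assert len(expected) == len(cfg.causal)  # simulation recovery: all causal, nothing else
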