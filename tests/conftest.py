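"""Shared fixtures: quick variant builders and a written default simulation."""

from __future__ import annotations

import pytest

from fnbfind import (
    DesignMode,
    GenotypeCall,
    SampleRoles,
    StudyDesign,
    Variant,
    classify_genotype,
)
from fnbfind.simulator import SimConfig, simulate_experiment


def make_variant(
    chrom="chr1",
    pos=100,
    ref="ATG",
    alt="A",
    qual=500.0,
    genotypes=None,
    gq=99,
    dp=30,
):
    """Variant with per-sample GT strings, uniform GQ/DP unless overridden."""
    calls = {}
    for sample, gt in (genotypes or {}).items():
        if isinstance(gt, tuple):
            gt, s_gq, s_dp = gt
        else:
            s_gq, s_dp = gq, dp
        calls[sample] = GenotypeCall(sample, classify_genotype(gt), s_gq, s_dp, gt)
    return Variant(chrom, pos, ref, alt, qual, calls)


@pytest.fixture
def roles_bsa():
    return SampleRoles(
        mutant_pool="mut_pool",
        wildtype_like_pool="wtl_pool",
        wildtype_control="A17",
        irrelevant_mutants=("irr1", "irr2"),
    )


@pytest.fixture
def design_bsa():
    return StudyDesign(DesignMode.RECESSIVE_BSA)


@pytest.fixture(scope="session")
def default_sim():
    """One default recessive-BSA experiment, reused read-only."""
    return simulate_experiment(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_sim_paths(default_sim, tmp_path_factory):
    """The same experiment written to disk (FASTA/GFF3/VCF/BEDs/truth)."""
    outdir = tmp_path_factory.mktemp("sim_default")
    return default_sim.write(outdir)
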