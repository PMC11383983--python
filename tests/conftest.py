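"""Shared fixtures: simulated datasets every test stage can reuse.

Everything is generated programmatically at test time; the heavyweight
simulations (null calibration across many genes) are session-scoped so they
run once.
"""

from __future__ import annotations

import pytest

from splicord.pipeline import RunConfig, analyze, introns_table, run_all, snps_to_phased
from splicord.simulate import simulate_gene_set, write_fixture

# study conditions for the simulated datasets (see docs/methods.md)
NULL_DEPTH = 150.0
POWER_DEPTH = 400.0
N_NULL_GENES = 230

SWAP_SETTINGS = {
    "order_mixture_hap1": {(0, 1, 2): 1.0},
    "order_mixture_hap2": {(1, 0, 2): 1.0},
}


@pytest.fixture(scope="session")
def swap_scenario():
    """Three genes: null / planted order swap + poly(A) + APA effects / null."""
    settings = [
        {},
        {
            **SWAP_SETTINGS,
            "polya_hap1": (233.0, 30.0),
            "polya_hap2": (143.0, 30.0),
        },
        {},
    ]
    reads, truth, models, snps = simulate_gene_set(settings, seed=11, depth=POWER_DEPTH)
    return reads, truth, models, snps


@pytest.fixture(scope="session")
def swap_fixture(tmp_path_factory, swap_scenario):
    """The swap scenario written to disk as SAM + VCF + BED + truth TSV."""
    reads, truth, models, snps = swap_scenario
    outdir = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(reads, truth, models, snps, str(outdir))
    return paths, truth, models


@pytest.fixture(scope="session")
def swap_results(swap_fixture, tmp_path_factory):
    """Full pipeline output over the on-disk swap fixture."""
    paths, _, _ = swap_fixture
    outdir = tmp_path_factory.mktemp("run")
    config = RunConfig(
        bam=paths["sam"], vcf=paths["vcf"], annotation=paths["bed"],
        outdir=str(outdir), seed=11,
    )
    return run_all(config), config


@pytest.fixture(scope="session")
def null_study():
    """Comparison table over many identically distributed allele pairs.

    One dataset (one BH family) of N_NULL_GENES null genes at NULL_DEPTH
    reads per allele; groups failing coverage filters drop out upstream.
    """
    reads, truth, models, snps = simulate_gene_set(
        [{} for _ in range(N_NULL_GENES)], seed=5, depth=NULL_DEPTH
    )
    res = analyze(
        [r.to_aligned_read() for r in reads], introns_table(models), snps_to_phased(snps)
    )
    return res
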