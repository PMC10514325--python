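"""Shared fixtures: toy tables and the desk-scale simulated study scenario."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from snpbridge.genome_io import Parameters, SiteRecord, VariantTable
from snpbridge.pipeline import run_reconciliation
from snpbridge.simulate import EditSpec, PanelSpec, default_scenario

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_site(contig="c1", pos1=5, ref="A", alt="G", qual=50.0, mq=50.0,
              genotypes=((0, 0), (0, 1))):
    return SiteRecord(contig, pos1, ref, alt, qual, mq, tuple(genotypes))


def make_table(sites, samples=("s1", "s2"), version="vA"):
    return VariantTable(version, tuple(samples), list(sites))


@pytest.fixture(scope="session")
def scenario():
    """The default desk-scale scenario: 2 x 500 kb, 60 samples, 2000 SNPs."""
    return default_scenario(11)


@pytest.fixture(scope="session")
def pipeline_result(scenario):
    return run_reconciliation(scenario.genome_a, scenario.genome_b,
                              scenario.table_a, scenario.table_b,
                              scenario.params)


@pytest.fixture(scope="session")
def small_scenario():
    """A fast small-genome scenario (30 kb contigs, short flanks) for tests
    that need a full assembly pair but not the default problem size."""
    edits = EditSpec(
        n_inversions=1, inversion_len=(1000, 2000),
        n_duplications=1, duplication_len=(1500, 2500),
        n_deletions=3, n_insertions=3, n_translocations=0,
        n_gaps=1, gap_len=(100, 200), end_margin=500,
    )
    panel = PanelSpec(n_samples=20, n_snps=80, missing_rate=0.01,
                      discordant_fraction=0.05, seed=9)
    params = Parameters(flank=200, seed=7)
    return default_scenario(7, contig_length=30_000, edits=edits,
                            panel=panel, params=params)


@pytest.fixture(scope="session")
def small_result(small_scenario):
    sc = small_scenario
    return run_reconciliation(sc.genome_a, sc.genome_b, sc.table_a,
                              sc.table_b, sc.params)
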