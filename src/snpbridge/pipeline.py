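"""End-to-end orchestration of the reconciliation stages.

Runs, in order: the post-calling filter on both callsets, flank extraction
from both assemblies, exact both-strand mapping of each flank into the
other assembly, reciprocal confirmation into SNP pairs, panel-wide genotype
concordance, and selection of the reliable set.
"""

from __future__ import annotations

from dataclasses import dataclass


from . import flank as flank_mod
from . import mapper as mapper_mod
from . import reconcile as reconcile_mod
from .genome_io import Parameters, ReferenceAssembly, VariantTable, filter_variants
from .merge import ReliableSet


@dataclass
class PipelineResult:
    filtered_a: VariantTable
    filtered_b: VariantTable
    filter_report_a: dict
    filter_report_b: dict
    flanks_a: list
    flanks_b: list
    flank_skips_a: list
    flank_skips_b: list
    maps_ab: dict
    maps_ba: dict
    map_summary_ab: dict
    map_summary_ba: dict
    pairs: list
    pair_report: dict
    concordances: list
    kept: list
    histogram: tuple
    tally: dict

    @property
    def reliable(self) -> ReliableSet:
        return ReliableSet(self.filtered_a.version_tag,
                           self.filtered_b.version_tag,
                           [r.pair for r in self.kept])

    @property
    def paired_set(self) -> ReliableSet:
        """All reciprocally confirmed pairs, before the concordance cut."""
        return ReliableSet(self.filtered_a.version_tag,
                           self.filtered_b.version_tag, list(self.pairs))


def run_reconciliation(
    genome_a: ReferenceAssembly,
    genome_b: ReferenceAssembly,
    table_a: VariantTable,
    table_b: VariantTable,
    params: Parameters | None = None,
    *,
    apply_filter: bool = True,
    full_panel_denominator: bool = False,
) -> PipelineResult:
    """Run the full reconciliation pipeline on two assemblies + callsets."""
    params = params or Parameters()
    if apply_filter:
        fa, rep_a = filter_variants(table_a, params)
        fb, rep_b = filter_variants(table_b, params)
    else:
        fa, rep_a = table_a, {"input": len(table_a), "kept": len(table_a)}
        fb, rep_b = table_b, {"input": len(table_b), "kept": len(table_b)}
    flanks_a, skips_a = flank_mod.extract_flanks(genome_a, fa, params.flank)
    flanks_b, skips_b = flank_mod.extract_flanks(genome_b, fb, params.flank)
    k = min(31, 2 * params.flank + 1)
    idx_b = mapper_mod.build_index(genome_b, k=k)
    idx_a = mapper_mod.build_index(genome_a, k=k)
    maps_ab = mapper_mod.map_flanks(flanks_a, idx_b, genome_b)
    maps_ba = mapper_mod.map_flanks(flanks_b, idx_a, genome_a)
    pairs, pair_report = reconcile_mod.pair_snps(maps_ab, maps_ba, fa, fb)
    concordances = reconcile_mod.concordance_all(
        pairs, fa, fb, params, full_panel_denominator=full_panel_denominator)
    kept, hist, tally = reconcile_mod.select_reliable(concordances, params)
    return PipelineResult(
        filtered_a=fa, filtered_b=fb,
        filter_report_a=rep_a, filter_report_b=rep_b,
        flanks_a=flanks_a, flanks_b=flanks_b,
        flank_skips_a=skips_a, flank_skips_b=skips_b,
        maps_ab=maps_ab, maps_ba=maps_ba,
        map_summary_ab=mapper_mod.summarize_mapping(maps_ab),
        map_summary_ba=mapper_mod.summarize_mapping(maps_ba),
        pairs=pairs, pair_report=pair_report,
        concordances=concordances, kept=kept, histogram=hist, tally=tally,
    )
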