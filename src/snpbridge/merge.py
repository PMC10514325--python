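"""Liftover of a callset across assembly versions through the reliable set,
and consolidation of callsets into one genotype matrix.

Liftover re-emits each site found in the reliable set at its partner
coordinates with the partner's REF/ALT; for strand-flipped pairs alleles are
complemented, and genotype allele indices are re-encoded so every sample's
base multiset is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome_io import (
    MISSING, Parameters, SiteRecord, VariantTable, complement,
)
from .reconcile import FLIPPED, PairedSnp


@dataclass
class ReliableSet:
    """The reliable SNP pairs, bound to their two version tags."""

    version_a: str
    version_b: str
    pairs: list[PairedSnp]

    def index_by(self, side: str) -> dict[tuple[str, int], PairedSnp]:
        idx: dict[tuple[str, int], PairedSnp] = {}
        for p in self.pairs:
            k = p.a if side == "a" else p.b
            idx[(k.contig, k.pos1)] = p
        return idx


def _reencode_genotypes(
    site: SiteRecord, dst_ref: str, dst_alt: str, flipped: bool,
) -> tuple:
    """Re-encode allele indices so each sample's base multiset is preserved."""
    base_to_idx = {dst_ref: 0, dst_alt: 1}
    index_map = {}
    for i, b in enumerate((site.ref, site.alt)):
        bb = complement(b) if flipped else b
        index_map[i] = base_to_idx[bb]
    out = []
    for g in site.genotypes:
        if g is MISSING:
            out.append(MISSING)
        else:
            out.append(tuple(sorted((index_map[g[0]], index_map[g[1]]))))
    return tuple(out)


def liftover_vcf(
    table: VariantTable, reliable: ReliableSet
) -> tuple[VariantTable, dict[str, int]]:
    """Lift a callset from one version's coordinates to the other's.

    The direction is inferred from the table's version tag. Sites absent
    from the reliable set, or whose alleles disagree with the paired record,
    are dropped and counted. The output is sorted by (contig, pos1).
    """
    if table.version_tag == reliable.version_a:
        src_side = "a"
        dst_version = reliable.version_b
    elif table.version_tag == reliable.version_b:
        src_side = "b"
        dst_version = reliable.version_a
    else:
        raise ValueError(
            f"table version {table.version_tag!r} matches neither side of the "
            f"reliable set ({reliable.version_a!r}/{reliable.version_b!r})"
        )
    idx = reliable.index_by(src_side)
    report = {"input": len(table.sites), "lifted": 0,
              "NOT_IN_RELIABLE_SET": 0, "ALLELE_SET_MISMATCH": 0}
    out_sites: list[SiteRecord] = []
    for s in table.sites:
        p = idx.get((s.contig, s.pos1))
        if p is None:
            report["NOT_IN_RELIABLE_SET"] += 1
            continue
        src = p.a if src_side == "a" else p.b
        dst = p.b if src_side == "a" else p.a
        if {s.ref, s.alt} != {src.ref, src.alt}:
            report["ALLELE_SET_MISMATCH"] += 1
            continue
        flipped = p.strand_relation == FLIPPED
        out_sites.append(SiteRecord(
            contig=dst.contig, pos1=dst.pos1, ref=dst.ref, alt=dst.alt,
            qual=s.qual, mq=s.mq,
            genotypes=_reencode_genotypes(s, dst.ref, dst.alt, flipped),
        ))
        report["lifted"] += 1
    return VariantTable(dst_version, table.samples, out_sites), report


@dataclass
class MergeResult:
    table: VariantTable        # merged matrix over the union of panels
    match_rates: pd.DataFrame  # contig, pos1, n_shared, rate
    report: dict


def merge_callsets(
    native_b: VariantTable,
    lifted_a: VariantTable,
    params: Parameters,
    labels: tuple[str, str] = ("B", "A"),
    dedupe: bool = False,
) -> MergeResult:
    """Consolidate two callsets in the same coordinates into one matrix.

    Sites are intersected by (contig, pos1) with equal unordered allele sets
    (allele-discordant collisions are dropped with a reason count); samples
    are the union, with accessions present in both panels kept as two
    panel-tagged columns (or collapsed to the column with fewer missing
    calls when ``dedupe``). Sites whose merged missing fraction exceeds
    ``params.merge_max_missing`` are excluded. For accessions shared by
    name, per-site genotype match rates across panels are computed over
    samples informative in both.
    """
    if native_b.version_tag != lifted_a.version_tag:
        raise ValueError(
            f"both callsets must share coordinates; got "
            f"{native_b.version_tag!r} vs {lifted_a.version_tag!r}"
        )
    idx_b = native_b.site_index()
    idx_a = lifted_a.site_index()
    common_keys = sorted(set(idx_b) & set(idx_a))
    report = {"sites_b": len(idx_b), "sites_a": len(idx_a),
              "intersected": 0, "ALLELE_DISCORDANT": 0,
              "EXCESS_MISSING": 0, "kept": 0}
    if not common_keys:
        raise ValueError(
            "zero intersected sites between the two callsets "
            f"({len(idx_b)} native vs {len(idx_a)} lifted records; "
            "check that the liftover targeted the same version)"
        )
    set_b = set(native_b.samples)
    set_a = set(lifted_a.samples)
    shared = [s for s in native_b.samples if s in set_a]
    shared_set = set(shared)
    only_a = [s for s in lifted_a.samples if s not in set_b]
    pos_b = {s: i for i, s in enumerate(native_b.samples)}
    pos_a = {s: i for i, s in enumerate(lifted_a.samples)}
    tag_b, tag_a = labels

    keep_b: set[str] = shared_set
    if dedupe:
        # per shared accession, keep the panel column with fewer missing calls
        miss_b = dict.fromkeys(shared, 0)
        miss_a = dict.fromkeys(shared, 0)
        for key in common_keys:
            sb, sa = idx_b[key], idx_a[key]
            for s in shared:
                if sb.genotypes[pos_b[s]] is MISSING:
                    miss_b[s] += 1
                if sa.genotypes[pos_a[s]] is MISSING:
                    miss_a[s] += 1
        keep_b = {s for s in shared if miss_b[s] <= miss_a[s]}
        merged_samples = list(native_b.samples) + only_a
    else:
        merged_samples = (
            [f"{s}|{tag_b}" if s in shared_set else s for s in native_b.samples]
            + [f"{s}|{tag_a}" if s in shared_set else s for s in lifted_a.samples]
        )

    merged_sites: list[SiteRecord] = []
    rate_rows = []
    for key in common_keys:
        sb, sa = idx_b[key], idx_a[key]
        if {sb.ref, sb.alt} != {sa.ref, sa.alt}:
            report["ALLELE_DISCORDANT"] += 1
            continue
        report["intersected"] += 1
        # re-encode the lifted panel onto the native record's REF/ALT
        if (sa.ref, sa.alt) == (sb.ref, sb.alt):
            gts_a = sa.genotypes
        else:  # REF/ALT roles swapped: 0 <-> 1
            gts_a = tuple(
                MISSING if g is MISSING else tuple(sorted((1 - g[0], 1 - g[1])))
                for g in sa.genotypes
            )
        if dedupe:
            genotypes = [
                sb.genotypes[pos_b[s]]
                if (s not in shared_set or s in keep_b) else gts_a[pos_a[s]]
                for s in native_b.samples
            ]
            genotypes += [gts_a[pos_a[s]] for s in only_a]
        else:
            genotypes = [sb.genotypes[pos_b[s]] for s in native_b.samples]
            genotypes += [gts_a[pos_a[s]] for s in lifted_a.samples]
        genotypes = tuple(genotypes)
        miss_frac = sum(1 for g in genotypes if g is MISSING) / len(genotypes)
        # cross-panel match rate over shared accessions informative in both
        n_shared = 0
        n_match = 0
        for s in shared:
            gb = sb.genotypes[pos_b[s]]
            ga = gts_a[pos_a[s]]
            if gb is MISSING or ga is MISSING:
                continue
            n_shared += 1
            if gb == ga:
                n_match += 1
        rate_rows.append({
            "contig": key[0], "pos1": key[1], "n_shared": n_shared,
            "rate": (n_match / n_shared) if n_shared else float("nan"),
        })
        if miss_frac > params.merge_max_missing:
            report["EXCESS_MISSING"] += 1
            continue
        merged_sites.append(SiteRecord(
            contig=sb.contig, pos1=sb.pos1, ref=sb.ref, alt=sb.alt,
            qual=sb.qual, mq=sb.mq, genotypes=genotypes,
        ))
        report["kept"] += 1
    merged = VariantTable(native_b.version_tag, tuple(merged_samples),
                          merged_sites)
    return MergeResult(merged, pd.DataFrame(rate_rows), report)


def write_genotype_matrix(table: VariantTable, path: str | Path,
                          header_lines: Sequence[str] = ()) -> None:
    """Plain matrix TSV: rows = sites, columns = samples; alt-allele dosage
    codes 0/1/2, NA for missing."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("contig\tpos1\tref\talt\t" + "\t".join(table.samples) + "\n")
        for s in table.sites:
            codes = ["NA" if g is MISSING else str(g[0] + g[1])
                     for g in s.genotypes]
            fh.write(f"{s.contig}\t{s.pos1}\t{s.ref}\t{s.alt}\t"
                     + "\t".join(codes) + "\n")


def write_match_rates(df: pd.DataFrame, path: str | Path,
                      header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
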