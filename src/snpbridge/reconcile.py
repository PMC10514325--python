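"""Reciprocal confirmation of cross-assembly SNP pairs and panel-wide
genotype concordance.

A SNP called against version A and a SNP called against version B are
accepted as the same site when each one's flank maps uniquely onto the
other's coordinate, the two strand calls agree, and the strand-adjusted
allele sets are equal. Genotypes are then compared sample by sample as
orientation-free base multisets (allele indices resolved to bases; bases
complemented once, on the B side, when the pair is strand-flipped), and the
fraction of informative samples that agree is the pair's concordance rate.
The reliable set keeps pairs whose rate reaches the (inclusive) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import (
    MISSING, Parameters, SiteRecord, VariantTable, complement,
)
from .mapper import FORWARD, MapResult, UNIQUE

SAME = "SAME"
FLIPPED = "FLIPPED"

# exclusion reason codes for pairing candidates
NOT_RECIPROCAL = "NOT_RECIPROCAL"
STRAND_CONFLICT = "STRAND_CONFLICT"
ALLELE_MISMATCH = "ALLELE_MISMATCH"
TARGET_SITE_ABSENT = "TARGET_SITE_ABSENT"


@dataclass(frozen=True)
class SiteKey:
    contig: str
    pos1: int
    ref: str
    alt: str


@dataclass
class PairedSnp:
    """A reciprocally confirmed cross-assembly SNP pair."""

    id: str
    a: SiteKey
    b: SiteKey
    strand_relation: str  # SAME | FLIPPED


@dataclass
class ConcordanceResult:
    pair: PairedSnp
    n_informative: int
    n_match: int
    rate: float | None  # None when n_informative < min_informative

    @property
    def defined(self) -> bool:
        return self.rate is not None


def pair_snps(
    maps_ab: Mapping[str, MapResult],
    maps_ba: Mapping[str, MapResult],
    table_a: VariantTable,
    table_b: VariantTable,
) -> tuple[list[PairedSnp], dict[str, int]]:
    """Mutually confirm A→B and B→A unique mappings into SNP pairs.

    Returns the pairs plus an exclusion report counting, per reason, the A
    sites that did not pair (including the mapping-stage UNMAPPED/MULTI
    statuses and sites with no flank, for conservation accounting).
    """
    sites_b = table_b.site_index()
    report = {"input": len(table_a.sites), "paired": 0, "NO_FLANK": 0,
              "UNMAPPED": 0, "MULTI": 0, TARGET_SITE_ABSENT: 0,
              NOT_RECIPROCAL: 0, STRAND_CONFLICT: 0, ALLELE_MISMATCH: 0}
    pairs: list[PairedSnp] = []
    for sa in table_a.sites:
        sid_a = sa.snp_id(table_a.version_tag)
        ra = maps_ab.get(sid_a)
        if ra is None:
            report["NO_FLANK"] += 1
            continue
        if ra.status != UNIQUE:
            report[ra.status] += 1
            continue
        key_b = (ra.occurrence.contig, ra.inferred_pos1)
        sb = sites_b.get(key_b)
        if sb is None:
            report[TARGET_SITE_ABSENT] += 1
            continue
        sid_b = sb.snp_id(table_b.version_tag)
        rb = maps_ba.get(sid_b)
        if (rb is None or rb.status != UNIQUE
                or (rb.occurrence.contig, rb.inferred_pos1) != (sa.contig, sa.pos1)):
            report[NOT_RECIPROCAL] += 1
            continue
        if ra.occurrence.strand != rb.occurrence.strand:
            report[STRAND_CONFLICT] += 1
            continue
        relation = SAME if ra.occurrence.strand == FORWARD else FLIPPED
        alleles_b = {sb.ref, sb.alt}
        if relation == FLIPPED:
            alleles_b = {complement(x) for x in alleles_b}
        if alleles_b != {sa.ref, sa.alt}:
            report[ALLELE_MISMATCH] += 1
            continue
        pairs.append(PairedSnp(
            id=f"{sid_a}~{sid_b}",
            a=SiteKey(sa.contig, sa.pos1, sa.ref, sa.alt),
            b=SiteKey(sb.contig, sb.pos1, sb.ref, sb.alt),
            strand_relation=relation,
        ))
        report["paired"] += 1
    return pairs, report


def harmonize_genotype(
    gt: tuple[int, int], ref: str, alt: str, strand_relation: str = SAME
) -> tuple[str, str]:
    """Resolve an allele-index pair to an orientation-free base multiset.

    Indices are replaced by their bases from (ref, alt); when the pair is
    FLIPPED each base is complemented. The result is a sorted base pair,
    hence free of both allele order and strand orientation.
    """
    if gt is MISSING:
        raise ValueError("cannot harmonize a missing genotype")
    alleles = (ref, alt)
    bases = []
    for i in gt:
        if i not in (0, 1):
            raise ValueError(f"allele index {i} outside {{0, 1}}")
        b = alleles[i]
        bases.append(complement(b) if strand_relation == FLIPPED else b)
    return tuple(sorted(bases))  # type: ignore[return-value]


def genotype_concordance(
    pair: PairedSnp,
    table_a: VariantTable,
    table_b: VariantTable,
    shared_samples: Sequence[str],
    params: Parameters,
    *,
    full_panel_denominator: bool = False,
    _sites_a: Mapping[tuple[str, int], SiteRecord] | None = None,
    _sites_b: Mapping[tuple[str, int], SiteRecord] | None = None,
) -> ConcordanceResult:
    """Panel-wide genotype match rate for one confirmed pair.

    A shared sample is informative when its call is non-missing in both
    callsets; it matches when the two harmonized base multisets agree (the
    B side complemented once for FLIPPED pairs). By default the rate's
    denominator is the informative samples; ``full_panel_denominator`` keeps
    the matches but divides by the full shared panel instead.
    """
    if not shared_samples:
        raise ValueError("no shared samples between the two callsets")
    sites_a = _sites_a if _sites_a is not None else table_a.site_index()
    sites_b = _sites_b if _sites_b is not None else table_b.site_index()
    sa = sites_a[(pair.a.contig, pair.a.pos1)]
    sb = sites_b[(pair.b.contig, pair.b.pos1)]
    ia = {s: i for i, s in enumerate(table_a.samples)}
    ib = {s: i for i, s in enumerate(table_b.samples)}
    n_informative = 0
    n_match = 0
    for sample in shared_samples:
        ga = sa.genotypes[ia[sample]]
        gb = sb.genotypes[ib[sample]]
        if ga is MISSING or gb is MISSING:
            continue
        n_informative += 1
        ha = harmonize_genotype(ga, sa.ref, sa.alt, SAME)
        hb = harmonize_genotype(gb, sb.ref, sb.alt, pair.strand_relation)
        if ha == hb:
            n_match += 1
    denom = len(shared_samples) if full_panel_denominator else n_informative
    rate = (n_match / denom) if n_informative >= params.min_informative else None
    return ConcordanceResult(pair, n_informative, n_match, rate)


def concordance_all(
    pairs: Iterable[PairedSnp],
    table_a: VariantTable,
    table_b: VariantTable,
    params: Parameters,
    shared_samples: Sequence[str] | None = None,
    **kwargs,
) -> list[ConcordanceResult]:
    if shared_samples is None:
        in_b = set(table_b.samples)
        shared_samples = [s for s in table_a.samples if s in in_b]
    sites_a = table_a.site_index()
    sites_b = table_b.site_index()
    return [
        genotype_concordance(p, table_a, table_b, shared_samples, params,
                             _sites_a=sites_a, _sites_b=sites_b, **kwargs)
        for p in pairs
    ]


def select_reliable(
    results: Sequence[ConcordanceResult], params: Parameters
) -> tuple[list[ConcordanceResult], tuple[np.ndarray, np.ndarray], dict]:
    """Keep pairs with a defined rate at or above the threshold (inclusive).

    Also returns the histogram of defined rates (20 bins on [0, 1]) and the
    four-way tally by (strand relation, above/below threshold).
    """
    kept = [r for r in results
            if r.defined and r.rate >= params.concordance_threshold]
    defined_rates = [r.rate for r in results if r.defined]
    hist = np.histogram(defined_rates, bins=20, range=(0.0, 1.0))
    tally: dict[tuple[str, bool], int] = {
        (SAME, True): 0, (SAME, False): 0, (FLIPPED, True): 0, (FLIPPED, False): 0,
    }
    for r in results:
        if r.defined:
            above = r.rate >= params.concordance_threshold
            tally[(r.pair.strand_relation, above)] += 1
    return kept, hist, tally


# ---------------------------------------------------------------------------
# TSV / VCF export of the reliable set
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("snp_id", "contig_a", "pos1_a", "ref_a", "alt_a", "contig_b",
                "pos1_b", "ref_b", "alt_b", "strand", "n_informative",
                "n_match", "rate")


def write_concordance_tsv(
    results: Sequence[ConcordanceResult], path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write pairs with their concordance as TSV (strand +/-, rate 6 dp)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in results:
            p = r.pair
            strand = "+" if p.strand_relation == SAME else "-"
            rate = "NA" if r.rate is None else f"{r.rate:.6f}"
            fh.write("\t".join(map(str, (
                p.id, p.a.contig, p.a.pos1, p.a.ref, p.a.alt,
                p.b.contig, p.b.pos1, p.b.ref, p.b.alt,
                strand, r.n_informative, r.n_match, rate,
            ))) + "\n")


def read_concordance_tsv(path: str | Path) -> list[ConcordanceResult]:
    out: list[ConcordanceResult] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("snp_id\t"):
                continue
            (sid, ca, pa, ra_, aa, cb, pb, rb_, ab, strand,
             n_inf, n_match, rate) = line.split("\t")
            pair = PairedSnp(
                id=sid,
                a=SiteKey(ca, int(pa), ra_, aa),
                b=SiteKey(cb, int(pb), rb_, ab),
                strand_relation=SAME if strand == "+" else FLIPPED,
            )
            out.append(ConcordanceResult(
                pair, int(n_inf), int(n_match),
                None if rate == "NA" else float(rate),
            ))
    return out


def write_known_sites_vcf(
    results: Sequence[ConcordanceResult], path: str | Path, side: str = "a",
    version_tag: str = "", header_lines: Sequence[str] = (),
) -> None:
    """Export the reliable set as a minimal sample-free known-sites VCF.

    ``side`` selects which assembly version's coordinates ("a" or "b") the
    records are written in; the file is suitable as a known-sites input for
    base quality score recalibration.
    """
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    rows = []
    for r in results:
        k = r.pair.a if side == "a" else r.pair.b
        rows.append((k.contig, k.pos1, k.ref, k.alt))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snpbridge known-sites export\n")
        if version_tag:
            fh.write(f"##snpbridge_version_tag={version_tag}\n")
        for line in header_lines:
            fh.write(f"##{line.lstrip('#')}\n")
        for ctg in dict.fromkeys(r[0] for r in rows):
            fh.write(f"##contig=<ID={ctg}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for ctg, pos1, ref, alt in rows:
            fh.write(f"{ctg}\t{pos1}\t.\t{ref}\t{alt}\t.\t.\t.\n")
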