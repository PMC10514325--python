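"""Data model and I/O for reference assemblies and multi-sample SNP callsets.

Coordinate convention: all in-memory arithmetic is 0-based half-open; every
position exposed in files or reports (``pos1``) is 1-based, following VCF.

Genotypes are unphased diploid calls over a biallelic site, stored as an
ordered (sorted) pair of allele indices from {0, 1}, or ``None`` when the
call is missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: a missing diploid call
MISSING = None

Genotype = Optional[tuple[int, int]]


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed; message names the line."""


def _check_alphabet(seq: str, context: str = "sequence") -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"illegal character(s) {sorted(bad)} in {context}; "
            "only A/C/G/T/N are allowed"
        )


def complement(seq: str) -> str:
    """Base-wise complement (no reversal); N maps to N."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement over A/C/G/T/N."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceAssembly:
    """A named, versioned collection of contig sequences over A/C/G/T/N."""

    version_tag: str
    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.version_tag:
            raise ValueError("version_tag must be non-empty")
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")
            _check_alphabet(seq, f"contig {name!r}")

    def __len__(self) -> int:
        return len(self.contigs)

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class SiteRecord:
    """One biallelic SNP with per-sample unphased diploid genotypes."""

    contig: str
    pos1: int
    ref: str
    alt: str
    qual: float
    mq: float
    genotypes: tuple[Genotype, ...]

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"REF/ALT must be single bases, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("REF and ALT must differ")
        if self.pos1 < 1:
            raise ValueError("positions are 1-based; pos1 must be >= 1")
        norm = []
        for gt in self.genotypes:
            if gt is MISSING:
                norm.append(MISSING)
                continue
            a, b = gt
            if a not in (0, 1) or b not in (0, 1):
                raise ValueError(f"allele indices must be 0 or 1, got {gt}")
            norm.append((a, b) if a <= b else (b, a))
        self.genotypes = tuple(norm)

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos1)

    def snp_id(self, version_tag: str) -> str:
        return f"{version_tag}|{self.contig}|{self.pos1}|{self.ref}|{self.alt}"


@dataclass
class VariantTable:
    """An ordered multi-sample SNP callset bound to one assembly version."""

    version_tag: str
    samples: tuple[str, ...]
    sites: list[SiteRecord]

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        n = len(self.samples)
        for s in self.sites:
            if len(s.genotypes) != n:
                raise ValueError(
                    f"site {s.contig}:{s.pos1} has {len(s.genotypes)} genotypes "
                    f"for {n} samples"
                )
        self.sites = sorted(self.sites, key=lambda s: (s.contig, s.pos1))

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def site_index(self) -> dict[tuple[str, int], SiteRecord]:
        """Map (contig, pos1) -> site; raises on duplicate keys."""
        idx: dict[tuple[str, int], SiteRecord] = {}
        for s in self.sites:
            if s.key in idx:
                raise ValueError(f"duplicate site key {s.key} in table {self.version_tag}")
            idx[s.key] = s
        return idx


@dataclass
class Parameters:
    """Every numeric setting of the pipeline, with its working default.

    ``flank`` is the half-width f of the probe window (2f+1 bases total);
    ``min_qual``/``min_mq``/``min_maf``/``max_missing_call`` are the strict
    post-calling filter thresholds; ``concordance_threshold`` is the
    inclusive genotype match-rate cut for the reliable set;
    ``merge_max_missing`` bounds per-site missingness in the merged matrix.
    """

    flank: int = 500
    min_qual: float = 30.0
    min_mq: float = 30.0
    min_maf: float = 0.02
    max_missing_call: float = 0.05
    concordance_threshold: float = 0.90
    min_informative: int = 1
    kmer_k: int = 3
    merge_max_missing: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError("flank must be >= 1")
        for name in ("min_maf", "max_missing_call", "concordance_threshold",
                     "merge_max_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_informative < 1:
            raise ValueError("min_informative must be >= 1")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, version_tag: str | None = None) -> ReferenceAssembly:
    """Read a (multi-record, wrapped or unwrapped) FASTA file.

    Lowercase bases are folded to uppercase. Any IUPAC ambiguity code other
    than N is rejected, naming the offending line.
    """
    path = Path(path)
    tag = version_tag or path.stem
    contigs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    header_line = 0

    def _close(lineno: int) -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: empty record {name!r} (header at line {header_line})"
            )
        contigs[name] = seq

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _close(lineno)
                header = line[1:].split()
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                name = header[0]
                if name in contigs:
                    raise FastaParseError(
                        f"{path}: duplicate contig name {name!r} at line {lineno}"
                    )
                header_line = lineno
                chunks = []
            else:
                if name is None:
                    raise FastaParseError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                up = line.upper()
                bad = set(up) - DNA_ALPHABET
                if bad:
                    raise FastaParseError(
                        f"{path}: illegal character(s) {sorted(bad)} at line {lineno}"
                    )
                chunks.append(up)
    if name is None:
        raise FastaParseError(f"{path}: no FASTA records found")
    _close(-1)
    return ReferenceAssembly(version_tag=tag, contigs=contigs)


def write_fasta(assembly: ReferenceAssembly, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in assembly.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, version_tag: str | None = None) -> VariantTable:
    """Load biallelic SNP records from a VCF 4.x file.

    Indel and multiallelic records are skipped with a logged count. Site MQ is
    taken from INFO/MQ; when absent, it loads as NaN (and then fails any
    strict MQ threshold). Genotype "./." (and half-missing calls) map to
    MISSING; "0/1" and "1/0" load to the same unordered pair.
    """
    path = Path(path)
    tag = version_tag
    with pysam.VariantFile(str(path)) as vf:
        if tag is None:
            # prefer the version tag recorded by write_vcf, if any
            for rec in vf.header.records:
                if rec.key == "snpbridge_version_tag" and rec.value:
                    tag = str(rec.value)
                    break
        if tag is None:
            tag = path.stem
        if "GT" not in vf.header.formats:
            raise ValueError(f"{path}: VCF has no GT FORMAT field")
        samples = tuple(vf.header.samples)
        has_mq = "MQ" in vf.header.info
        sites: list[SiteRecord] = []
        n_skipped = 0
        for rec in vf:
            alts = rec.alts or ()
            if (len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1
                    or rec.ref not in BASES or alts[0] not in BASES):
                n_skipped += 1
                continue
            mq = rec.info.get("MQ", None) if has_mq else None
            if isinstance(mq, tuple):
                mq = mq[0] if mq else None
            genotypes: list[Genotype] = []
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or len(gt) != 2 or None in gt:
                    genotypes.append(MISSING)
                else:
                    genotypes.append(tuple(sorted(gt)))  # type: ignore[arg-type]
            sites.append(SiteRecord(
                contig=rec.chrom,
                pos1=rec.pos,
                ref=rec.ref,
                alt=alts[0],
                qual=float(rec.qual) if rec.qual is not None else 0.0,
                mq=float(mq) if mq is not None else math.nan,
                genotypes=tuple(genotypes),
            ))
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic-SNP record(s)", path, n_skipped)
    return VariantTable(version_tag=tag, samples=samples, sites=sites)


def _fmt_num(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "."
    return f"{x:.10g}"


def write_vcf(
    table: VariantTable,
    path: str | Path,
    assembly: ReferenceAssembly | None = None,
    extra_header: Sequence[str] = (),
) -> None:
    """Write a VariantTable as plain-text VCF 4.2 (GT only, INFO/MQ)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snpbridge\n")
        fh.write(f"##snpbridge_version_tag={table.version_tag}\n")
        for line in extra_header:
            fh.write(f"##{line.lstrip('#')}\n")
        contigs = dict.fromkeys(s.contig for s in table.sites)
        for ctg in contigs:
            if assembly is not None and ctg in assembly.contigs:
                fh.write(f"##contig=<ID={ctg},length={len(assembly.contigs[ctg])}>\n")
            else:
                fh.write(f"##contig=<ID={ctg}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        cols += list(table.samples)
        fh.write("\t".join(cols) + "\n")
        for s in table.sites:
            info = "." if math.isnan(s.mq) else f"MQ={_fmt_num(s.mq)}"
            gts = ["./." if g is MISSING else f"{g[0]}/{g[1]}" for g in s.genotypes]
            row = [s.contig, str(s.pos1), ".", s.ref, s.alt, _fmt_num(s.qual),
                   ".", info, "GT"] + gts
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Post-calling filter and saturation
# ---------------------------------------------------------------------------

def site_stats(site: SiteRecord) -> tuple[float, float]:
    """Return (MAF, missing fraction) for a site.

    MAF is the lesser allele frequency over non-missing allele calls (two per
    called sample); with zero called samples MAF is 0.
    """
    n_samples = len(site.genotypes)
    called = [g for g in site.genotypes if g is not MISSING]
    missing_frac = (n_samples - len(called)) / n_samples
    if not called:
        return 0.0, missing_frac
    alt_calls = sum(a + b for a, b in called)
    total_calls = 2 * len(called)
    f_alt = alt_calls / total_calls
    return min(f_alt, 1.0 - f_alt), missing_frac


def site_passes_filter(site: SiteRecord, params: Parameters) -> bool:
    """Strict post-calling criteria: QUAL>t, MQ>t, MAF>t, missing<t."""
    maf, miss = site_stats(site)
    return (site.qual > params.min_qual and site.mq > params.min_mq
            and maf > params.min_maf and miss < params.max_missing_call)


def filter_variants(
    table: VariantTable, params: Parameters
) -> tuple[VariantTable, dict[str, int]]:
    """Apply the strict post-calling filter; returns (table, report).

    The report counts, per criterion, how many sites fail it (a site failing
    several criteria is counted under each).
    """
    if not table.samples:
        raise ValueError("cannot filter a table with zero samples")
    report = {"input": len(table.sites), "kept": 0, "fail_qual": 0,
              "fail_mq": 0, "fail_maf": 0, "fail_missing": 0}
    kept: list[SiteRecord] = []
    for s in table.sites:
        maf, miss = site_stats(s)
        ok = True
        if not s.qual > params.min_qual:
            report["fail_qual"] += 1
            ok = False
        if not s.mq > params.min_mq:
            report["fail_mq"] += 1
            ok = False
        if not maf > params.min_maf:
            report["fail_maf"] += 1
            ok = False
        if not miss < params.max_missing_call:
            report["fail_missing"] += 1
            ok = False
        if ok:
            kept.append(s)
    report["kept"] = len(kept)
    return VariantTable(table.version_tag, table.samples, kept), report


def snp_saturation(
    table: VariantTable,
    order: Sequence[str] | None = None,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """SNP discovery curve as samples accumulate.

    ``count[k-1]`` is the number of sites at which at least one of the first
    k samples carries a non-missing genotype containing the alternate allele.
    With ``order`` given it is computed for that sample ordering; with
    ``n_permutations`` the mean curve over seeded random orderings is
    returned.
    """
    samples = list(table.samples)
    n = len(samples)
    if order is not None and len(order) == 0:
        raise ValueError("order must be non-empty")
    if order is None and not n_permutations:
        raise ValueError("provide either an explicit order or n_permutations")
    # per site: indices of samples carrying allele 1
    carriers = [
        [i for i, g in enumerate(s.genotypes) if g is not MISSING and 1 in g]
        for s in table.sites
    ]

    def curve_for(perm: Sequence[int]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(perm)}
        firsts = np.full(len(carriers), -1, dtype=np.int64)
        for j, carr in enumerate(carriers):
            if carr:
                firsts[j] = min(pos[i] for i in carr)
        counts = np.zeros(len(perm), dtype=np.int64)
        for f in firsts:
            if f >= 0:
                counts[f] += 1
        return np.cumsum(counts)

    if order is not None:
        if sorted(order) != sorted(samples):
            raise ValueError("order must be a permutation of the table's samples")
        idx_order = [samples.index(s) for s in order]
        return curve_for(idx_order)
    rng = np.random.default_rng(seed)
    acc = np.zeros(n, dtype=np.float64)
    for _ in range(n_permutations):
        acc += curve_for(rng.permutation(n))
    return acc / n_permutations
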