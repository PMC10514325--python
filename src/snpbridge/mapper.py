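"""Exact both-strand occurrence search of flank probes in a target assembly.

The contract is completeness: for a query Q, every interval of the target
equal to Q (forward) or to revcomp(Q) (reverse) is reported, full length,
zero mismatches. A k-mer seed table accelerates the search; the seed taken
at the center of the query generates candidates which are then verified over
the full query length, so the result set equals a naive scan of both
strands.

A unique occurrence transfers the SNP coordinate: because the probe is a
symmetric (2f+1)-mer, its center sits at offset f from the match start under
either orientation, so ``inferred_pos1 = start0 + f + 1`` for both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .flank import FlankRecord
from .genome_io import ReferenceAssembly, revcomp

FORWARD = "+"
REVERSE = "-"

UNIQUE = "UNIQUE"
UNMAPPED = "UNMAPPED"
MULTI = "MULTI"

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Occurrence:
    contig: str
    start0: int
    strand: str


@dataclass
class MapResult:
    snp_id: str
    status: str
    occurrence: Occurrence | None = None
    inferred_pos1: int | None = None
    inferred_base: str | None = None


class SeqIndex:
    """Forward-strand k-mer seed table of a target assembly.

    k-mers containing N are not indexed; every position of every indexable
    k-mer is listed exactly once (2-bit integer encoding, no hashing
    collisions).
    """

    def __init__(self, target_version: str, k: int,
                 table: dict[int, list[tuple[str, int]]]):
        self.target_version = target_version
        self.k = k
        self.table = table


def encode_kmer(kmer: str) -> int:
    """2-bit encode a k-mer over A/C/G/T; raises on N or other characters."""
    val = 0
    for ch in kmer:
        c = _CODE.get(ch)
        if c is None:
            raise ValueError(f"cannot encode character {ch!r}")
        val = (val << 2) | c
    return val


def build_index(assembly: ReferenceAssembly, k: int = 31) -> SeqIndex:
    """Index every N-free k-mer of the assembly's forward strand."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if all(len(seq) < k for seq in assembly.contigs.values()):
        raise ValueError(f"k={k} exceeds the length of every contig")
    mask = (1 << (2 * k)) - 1
    table: dict[int, list[tuple[str, int]]] = {}
    setdefault = table.setdefault
    for name, seq in assembly.contigs.items():
        val = 0
        run = 0
        for i, ch in enumerate(seq):
            c = _CODE.get(ch)
            if c is None:  # N resets the rolling window
                run = 0
                val = 0
                continue
            val = ((val << 2) | c) & mask
            run += 1
            if run >= k:
                setdefault(val, []).append((name, i - k + 1))
    return SeqIndex(assembly.version_tag, k, table)


def find_exact_occurrences(
    index: SeqIndex, assembly: ReferenceAssembly, query: str
) -> list[Occurrence]:
    """All full-length exact occurrences of ``query`` on both strands."""
    if "N" in query:
        raise ValueError("query must not contain N")
    L = len(query)
    k = index.k
    if L < k:
        raise ValueError(f"query length {L} is shorter than the seed length {k}")
    c = (L - k) // 2  # center seed offset
    out: list[Occurrence] = []
    for strand, q in ((FORWARD, query), (REVERSE, revcomp(query))):
        seed = encode_kmer(q[c:c + k])
        for ctg, pos in index.table.get(seed, ()):
            s = pos - c
            if s < 0:
                continue
            seq = assembly.contigs[ctg]
            if s + L <= len(seq) and seq[s:s + L] == q:
                out.append(Occurrence(ctg, s, strand))
    out.sort(key=lambda o: (o.contig, o.start0, o.strand))
    return out


def map_flank(
    flank: FlankRecord, index: SeqIndex, target: ReferenceAssembly
) -> MapResult:
    """Classify a flank as UNIQUE / UNMAPPED / MULTI in the target assembly."""
    occs = find_exact_occurrences(index, target, flank.seq)
    if not occs:
        return MapResult(flank.snp_id, UNMAPPED)
    if len(occs) > 1:
        return MapResult(flank.snp_id, MULTI)
    occ = occs[0]
    pos0 = occ.start0 + flank.center_offset
    return MapResult(
        snp_id=flank.snp_id,
        status=UNIQUE,
        occurrence=occ,
        inferred_pos1=pos0 + 1,
        inferred_base=target.contigs[occ.contig][pos0],
    )


def map_flanks(
    flanks: Iterable[FlankRecord], index: SeqIndex, target: ReferenceAssembly
) -> dict[str, MapResult]:
    return {fl.snp_id: map_flank(fl, index, target) for fl in flanks}


def summarize_mapping(results: Mapping[str, MapResult]) -> dict[str, float]:
    """Fractions of flanks mapped uniquely / unmapped / multi-mapped."""
    n = len(results)
    counts = {UNIQUE: 0, UNMAPPED: 0, MULTI: 0}
    for r in results.values():
        counts[r.status] += 1
    if n == 0:
        return {"n": 0, "frac_unique": 0.0, "frac_unmapped": 0.0, "frac_multi": 0.0}
    return {
        "n": n,
        "frac_unique": counts[UNIQUE] / n,
        "frac_unmapped": counts[UNMAPPED] / n,
        "frac_multi": counts[MULTI] / n,
    }


def write_map_results(results: Mapping[str, MapResult], path: str | Path,
                      header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("snp_id\tstatus\ttarget_contig\ttarget_pos1\tstrand\ttarget_base\n")
        for sid, r in results.items():
            if r.status == UNIQUE:
                fh.write(f"{sid}\t{r.status}\t{r.occurrence.contig}\t"
                         f"{r.inferred_pos1}\t{r.occurrence.strand}\t{r.inferred_base}\n")
            else:
                fh.write(f"{sid}\t{r.status}\t.\t.\t.\t.\n")


def read_map_results(path: str | Path) -> dict[str, MapResult]:
    results: dict[str, MapResult] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("snp_id\t"):
                continue
            sid, status, ctg, pos1, strand, base = line.split("\t")
            if status == UNIQUE:
                # start0 is not stored in the TSV; downstream pairing needs
                # only the strand and the inferred position.
                occ = Occurrence(ctg, -1, strand)
                results[sid] = MapResult(sid, status, occ, int(pos1), base)
            else:
                results[sid] = MapResult(sid, status)
    return results
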