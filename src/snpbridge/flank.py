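"""Symmetric flank extraction: the 2f+1-base probe window around each SNP.

The window carries f reference bases on each side of the SNP and the SNP's
own reference base at its center; it is the unit that gets searched for in
the other assembly version.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .genome_io import ReferenceAssembly, VariantTable

SKIP_LEFT = "insufficient_left_context"
SKIP_RIGHT = "insufficient_right_context"
SKIP_N = "contains_N"
SKIP_REF_MISMATCH = "ref_mismatch"


@dataclass
class FlankRecord:
    """A 2f+1-long sequence centered on a SNP's reference base."""

    snp_id: str
    source_version: str
    contig: str
    pos1: int
    center_offset: int  # = f
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != 2 * self.center_offset + 1:
            raise ValueError(
                f"flank for {self.snp_id} has length {len(self.seq)}, "
                f"expected {2 * self.center_offset + 1}"
            )


@dataclass
class FlankSkip:
    snp_id: str
    reason: str


def extract_flanks(
    assembly: ReferenceAssembly, table: VariantTable, f: int
) -> tuple[list[FlankRecord], list[FlankSkip]]:
    """Extract the symmetric flank of every eligible site.

    A site is skipped (with a reason) when fewer than f bases exist on either
    side of it, when the window contains any N, or when the assembly base at
    the site differs from the recorded REF (inconsistent inputs).
    """
    if f < 1:
        raise ValueError("flank half-width must be >= 1")
    if table.version_tag != assembly.version_tag:
        raise ValueError(
            f"table version {table.version_tag!r} does not match assembly "
            f"{assembly.version_tag!r}"
        )
    records: list[FlankRecord] = []
    skips: list[FlankSkip] = []
    for s in table.sites:
        if s.contig not in assembly.contigs:
            raise KeyError(f"contig {s.contig!r} absent from assembly "
                           f"{assembly.version_tag!r}")
        seq = assembly.contigs[s.contig]
        c0 = s.pos1 - 1
        sid = s.snp_id(table.version_tag)
        if c0 - f < 0:
            skips.append(FlankSkip(sid, SKIP_LEFT))
            continue
        if c0 + f >= len(seq):
            skips.append(FlankSkip(sid, SKIP_RIGHT))
            continue
        if seq[c0] != s.ref:
            skips.append(FlankSkip(sid, SKIP_REF_MISMATCH))
            continue
        window = seq[c0 - f: c0 + f + 1]
        if "N" in window:
            skips.append(FlankSkip(sid, SKIP_N))
            continue
        records.append(FlankRecord(
            snp_id=sid, source_version=table.version_tag, contig=s.contig,
            pos1=s.pos1, center_offset=f, seq=window,
        ))
    return records, skips


def skip_counts(skips: Sequence[FlankSkip]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for sk in skips:
        counts[sk.reason] = counts.get(sk.reason, 0) + 1
    return counts


def write_flank_fasta(records: Sequence[FlankRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.snp_id}\n{r.seq}\n")


def read_flank_fasta(path: str | Path) -> list[FlankRecord]:
    """Re-load flank records written by :func:`write_flank_fasta`.

    The snp_id header (version|contig|pos1|ref|alt) carries the provenance;
    the center offset is recovered from the sequence length.
    """
    records: list[FlankRecord] = []
    name = None
    seq_parts: list[str] = []

    def close() -> None:
        if name is None:
            return
        seq = "".join(seq_parts)
        version, contig, pos1, _ref, _alt = name.split("|")
        records.append(FlankRecord(
            snp_id=name, source_version=version, contig=contig,
            pos1=int(pos1), center_offset=(len(seq) - 1) // 2, seq=seq,
        ))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                close()
                name = line[1:].split()[0]
                seq_parts = []
            else:
                seq_parts.append(line.upper())
    close()
    return records


def write_skip_report(skips: Sequence[FlankSkip], path: str | Path,
                      header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("snp_id\treason\n")
        for sk in skips:
            fh.write(f"{sk.snp_id}\t{sk.reason}\n")
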