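"""Paired-assembly simulation with ground truth.

Generates a random reference assembly, derives a second "updated" assembly
from it by tracked edits (point substitutions, small indels, inversions,
tandem duplications, a translocation, N-gap insertions), and simulates
matched multi-sample SNP callsets against both versions from one shared set
of underlying diploid genotypes. The exact base-level correspondence between
the two assemblies is recorded in a TruthMap, and every simulated site
carries a ground-truth label for its expected fate in the reconciliation
pipeline, so precision and recall of the reliable set can be measured.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import (
    BASES, MISSING, Parameters, ReferenceAssembly, SiteRecord, VariantTable,
    complement, revcomp, site_passes_filter,
)
from .reconcile import PairedSnp

# truth labels: a site's expected fate in the pipeline
TRANSFERABLE_CONCORDANT = "TRANSFERABLE_CONCORDANT"
EXPECT_MULTI = "EXPECT_MULTI"
EXPECT_UNMAPPED = "EXPECT_UNMAPPED"
EXPECT_DISCORDANT = "EXPECT_DISCORDANT"
EXPECT_FILTERED = "EXPECT_FILTERED"

_BYTE_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Truth map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthSegment:
    """One mapped interval pair between assemblies A and B.

    Coordinates are 0-based half-open; for strand "-" the base at A position
    a maps to B position ``b_start0 + (a_end0 - 1 - a)``. ``ambiguous``
    marks one-to-many mappings (tandem-duplication source regions).
    """

    contig_a: str
    a_start0: int
    a_end0: int
    contig_b: str
    b_start0: int
    b_end0: int
    strand: str  # "+" | "-"
    ambiguous: bool = False

    def project(self, pos0: int) -> int:
        if self.strand == "+":
            return self.b_start0 + (pos0 - self.a_start0)
        return self.b_start0 + (self.a_end0 - 1 - pos0)


@dataclass(frozen=True)
class Projection:
    contig_b: str
    pos0_b: int
    strand: str
    ambiguous: bool
    mismatch: bool


class TruthMap:
    """Piecewise interval correspondence between paired assemblies.

    Non-ambiguous segments are non-overlapping within each assembly;
    ambiguous (duplication-source) segments may share their A interval.
    ``substitutions`` records A positions whose base was changed in B
    (mapped, but mismatching).
    """

    def __init__(self, segments: Sequence[TruthSegment],
                 substitutions: Mapping[tuple[str, int], str] | None = None):
        self.segments = list(segments)
        self.substitutions = dict(substitutions or {})
        self._by_contig_a: dict[str, list[TruthSegment]] = {}
        for seg in self.segments:
            self._by_contig_a.setdefault(seg.contig_a, []).append(seg)
        for segs in self._by_contig_a.values():
            segs.sort(key=lambda s: (s.a_start0, s.b_start0))
        self._subs_by_contig: dict[str, list[int]] = {}
        for (ctg, pos) in self.substitutions:
            self._subs_by_contig.setdefault(ctg, []).append(pos)
        for v in self._subs_by_contig.values():
            v.sort()

    def project(self, contig: str, pos0: int) -> list[Projection]:
        """All B images of an A base (empty for unmapped gaps)."""
        out = []
        for seg in self._by_contig_a.get(contig, ()):
            if seg.a_start0 <= pos0 < seg.a_end0:
                out.append(Projection(
                    seg.contig_b, seg.project(pos0), seg.strand, seg.ambiguous,
                    (contig, pos0) in self.substitutions,
                ))
        return out

    def inverse(self) -> "TruthMap":
        """Swap the roles of the two assemblies (substitutions re-keyed to
        their B coordinates; ambiguous one-to-many stays ambiguous)."""
        segs = [TruthSegment(s.contig_b, s.b_start0, s.b_end0,
                             s.contig_a, s.a_start0, s.a_end0,
                             s.strand, s.ambiguous) for s in self.segments]
        subs = {}
        for (ctg, pos), base in self.substitutions.items():
            for pr in self.project(ctg, pos):
                subs[(pr.contig_b, pr.pos0_b)] = base
        return TruthMap(segs, subs)

    def _subs_in(self, contig: str, start0: int, end0: int) -> int:
        v = self._subs_by_contig.get(contig, [])
        return bisect.bisect_left(v, end0) - bisect.bisect_left(v, start0)

    def clean_segment(self, contig: str, start0: int, end0: int,
                      ignore_substitutions: bool = False
                      ) -> TruthSegment | None:
        """The unique non-ambiguous segment wholly containing the window,
        or None. Unless ignored, any substitution in the window disqualifies
        it."""
        for seg in self._by_contig_a.get(contig, ()):
            if seg.ambiguous:
                continue
            if seg.a_start0 <= start0 and end0 <= seg.a_end0:
                if not ignore_substitutions and self._subs_in(contig, start0, end0):
                    return None
                return seg
        return None


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class EditSpec:
    """Edit burden applied when deriving the updated assembly."""

    substitution_rate: float = 5e-4
    n_insertions: int = 10
    n_deletions: int = 10
    indel_len: tuple[int, int] = (1, 10)
    n_inversions: int = 3
    inversion_len: tuple[int, int] = (1000, 10000)
    n_duplications: int = 3
    duplication_len: tuple[int, int] = (2000, 5000)
    n_translocations: int = 1
    translocation_len: tuple[int, int] = (2000, 5000)
    n_gaps: int = 2
    gap_len: tuple[int, int] = (200, 500)
    end_margin: int = 1500


@dataclass
class PanelSpec:
    """Variant-panel simulation settings (two matched callsets)."""

    n_samples: int = 60
    n_snps: int = 2000
    af_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.005
    discordant_fraction: float = 0.02
    discordant_error_rate: float = 0.5
    multi_fraction: float = 0.025
    unmapped_fraction: float = 0.05
    lowqual_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "genotype_error_rate",
                     "discordant_fraction", "discordant_error_rate",
                     "multi_fraction", "unmapped_fraction", "lowqual_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SiteTruth:
    """Ground truth for one simulated SNP site."""

    snp_id_a: str
    contig_a: str
    pos1_a: int
    contig_b: str | None
    pos1_b: int | None
    strand: str | None  # "+" | "-" | None when no unique B coordinate
    label: str


# ---------------------------------------------------------------------------
# Reference and derived-assembly simulation
# ---------------------------------------------------------------------------

def simulate_reference(
    lengths: Mapping[str, int] | Sequence[int], seed: int,
    version_tag: str = "simA",
) -> ReferenceAssembly:
    """I.i.d. uniform A/C/G/T contigs, reproducible under the seed."""
    if not isinstance(lengths, Mapping):
        lengths = {f"chr{i + 1:02d}": int(n) for i, n in enumerate(lengths)}
    rng = np.random.default_rng(seed)
    contigs = {}
    for name, n in lengths.items():
        if n < 1:
            raise ValueError(f"contig length must be >= 1, got {n} for {name!r}")
        idx = rng.integers(0, 4, size=n)
        contigs[name] = _BYTE_BASES[idx].tobytes().decode("ascii")
    return ReferenceAssembly(version_tag, contigs)


@dataclass
class _Feature:
    kind: str          # inversion|duplication|deletion|trans_src|insertion|gap|trans_dst
    contig: str
    start0: int
    end0: int          # == start0 for point features
    payload: object = None


def _place_interval(rng, occupied: dict[str, list[tuple[int, int]]],
                    lengths: Mapping[str, int], length: int, margin: int,
                    contig: str | None = None) -> tuple[str, int]:
    names = list(lengths)
    for _ in range(2000):
        ctg = contig if contig is not None else names[rng.integers(len(names))]
        L = lengths[ctg]
        lo, hi = margin, L - margin - length
        if hi <= lo:
            continue
        s = int(rng.integers(lo, hi))
        e = s + max(length, 1)
        if all(e <= os or oe <= s for os, oe in occupied[ctg]):
            occupied[ctg].append((s, e))
            return ctg, s
    raise ValueError(
        "could not place an edit region: edit demands exceed the genome length"
    )


def derive_assembly(
    genome_a: ReferenceAssembly, edits: EditSpec, seed: int,
    version_tag: str = "simB",
) -> tuple[ReferenceAssembly, TruthMap]:
    """Derive an updated assembly by tracked edits, with exact ground truth.

    Edit regions are sampled without overlap and away from contig ends.
    Substituted bases stay mapped (flagged as mismatches); duplication
    sources map one-to-many and are marked ambiguous; deleted bases and the
    content of insertions/N-gaps have no correspondence.
    """
    rng = np.random.default_rng(seed)
    lengths = {n: len(s) for n, s in genome_a.contigs.items()}
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in lengths}
    features: dict[str, list[_Feature]] = {n: [] for n in lengths}
    margin = edits.end_margin

    def rand_len(lo_hi: tuple[int, int]) -> int:
        lo, hi = lo_hi
        return int(rng.integers(lo, hi + 1))

    for _ in range(edits.n_inversions):
        ln = rand_len(edits.inversion_len)
        ctg, s = _place_interval(rng, occupied, lengths, ln, margin)
        features[ctg].append(_Feature("inversion", ctg, s, s + ln))
    for _ in range(edits.n_duplications):
        ln = rand_len(edits.duplication_len)
        ctg, s = _place_interval(rng, occupied, lengths, ln, margin)
        features[ctg].append(_Feature("duplication", ctg, s, s + ln))
    for _ in range(edits.n_deletions):
        ln = rand_len(edits.indel_len)
        ctg, s = _place_interval(rng, occupied, lengths, ln, margin)
        features[ctg].append(_Feature("deletion", ctg, s, s + ln))
    for _ in range(edits.n_translocations):
        ln = rand_len(edits.translocation_len)
        src_ctg, s = _place_interval(rng, occupied, lengths, ln, margin)
        dst_ctg, p = _place_interval(rng, occupied, lengths, 1, margin)
        src_seq = genome_a.contigs[src_ctg][s:s + ln]
        features[src_ctg].append(_Feature("trans_src", src_ctg, s, s + ln))
        features[dst_ctg].append(_Feature(
            "trans_dst", dst_ctg, p, p, payload=(src_ctg, s, src_seq)))
    for _ in range(edits.n_insertions):
        ln = rand_len(edits.indel_len)
        ctg, p = _place_interval(rng, occupied, lengths, 1, margin)
        ins = _BYTE_BASES[rng.integers(0, 4, size=ln)].tobytes().decode()
        features[ctg].append(_Feature("insertion", ctg, p, p, payload=ins))
    for _ in range(edits.n_gaps):
        ln = rand_len(edits.gap_len)
        ctg, p = _place_interval(rng, occupied, lengths, 1, margin)
        features[ctg].append(_Feature("gap", ctg, p, p, payload="N" * ln))

    # point substitutions, outside all feature regions
    substitutions: dict[tuple[str, int], str] = {}
    subs_by_contig: dict[str, list[tuple[int, str]]] = {n: [] for n in lengths}
    for ctg, L in lengths.items():
        n_subs = rng.binomial(L, edits.substitution_rate)
        if n_subs == 0:
            continue
        positions = rng.choice(L, size=n_subs, replace=False)
        occ = occupied[ctg]
        for p in sorted(int(x) for x in positions):
            if any(os <= p < oe for os, oe in occ):
                continue
            old = genome_a.contigs[ctg][p]
            new = BASES[(BASES.index(old) + int(rng.integers(1, 4))) % 4]
            substitutions[(ctg, p)] = new
            subs_by_contig[ctg].append((p, new))

    # build assembly B contig by contig
    contigs_b: dict[str, str] = {}
    segments: list[TruthSegment] = []
    for ctg, L in lengths.items():
        seq_a = genome_a.contigs[ctg]
        evs = sorted(features[ctg], key=lambda f: (f.start0, f.end0))
        parts: list[str] = []
        b_pos = 0
        cur = 0
        sub_list = subs_by_contig[ctg]

        def emit(seq: str, a_ctg: str | None, a_s: int, a_e: int,
                 strand: str, ambiguous: bool) -> None:
            nonlocal b_pos
            if not seq:
                return
            if a_ctg is not None:
                segments.append(TruthSegment(
                    a_ctg, a_s, a_e, ctg, b_pos, b_pos + len(seq),
                    strand, ambiguous))
            parts.append(seq)
            b_pos += len(seq)

        def emit_plain(a_s: int, a_e: int) -> None:
            if a_e <= a_s:
                return
            block = seq_a[a_s:a_e]
            lo = bisect.bisect_left(sub_list, (a_s, ""))
            hi = bisect.bisect_left(sub_list, (a_e, ""))
            if lo != hi:
                chars = list(block)
                for p, new in sub_list[lo:hi]:
                    chars[p - a_s] = new
                block = "".join(chars)
            emit(block, ctg, a_s, a_e, "+", False)

        for ev in evs:
            emit_plain(cur, ev.start0)
            if ev.kind == "inversion":
                emit(revcomp(seq_a[ev.start0:ev.end0]), ctg,
                     ev.start0, ev.end0, "-", False)
            elif ev.kind == "duplication":
                dup = seq_a[ev.start0:ev.end0]
                emit(dup, ctg, ev.start0, ev.end0, "+", True)
                emit(dup, ctg, ev.start0, ev.end0, "+", True)
            elif ev.kind in ("deletion", "trans_src"):
                pass  # removed here; trans_src re-emitted at its destination
            elif ev.kind == "trans_dst":
                src_ctg, src_s, src_seq = ev.payload
                emit(src_seq, src_ctg, src_s, src_s + len(src_seq), "+", False)
            elif ev.kind in ("insertion", "gap"):
                emit(ev.payload, None, 0, 0, "+", False)
            cur = ev.end0
        emit_plain(cur, L)
        contigs_b[ctg] = "".join(parts)

    return (ReferenceAssembly(version_tag, contigs_b),
            TruthMap(segments, substitutions))


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

def _draw_genotypes(rng, af: float, n: int) -> np.ndarray:
    """Hardy-Weinberg alt-allele dosages (0/1/2) at allele frequency af."""
    return rng.binomial(2, af, size=n)


_GTS = ((0, 0), (0, 1), (1, 1))


def _panel_calls(rng, dosages: np.ndarray, error_rate: float,
                 missing_rate: float) -> list:
    """Apply per-sample genotype error then missingness to shared dosages."""
    n = len(dosages)
    calls = [_GTS[d] for d in dosages]
    err = rng.random(n) < error_rate
    for i in np.nonzero(err)[0]:
        others = [g for g in _GTS if g != calls[i]]
        calls[i] = others[int(rng.integers(len(others)))]
    miss = rng.random(n) < missing_rate
    for i in np.nonzero(miss)[0]:
        calls[i] = MISSING
    return calls


def simulate_panels(
    genome_a: ReferenceAssembly,
    genome_b: ReferenceAssembly,
    truth: TruthMap,
    spec: PanelSpec,
    params: Parameters | None = None,
) -> tuple[VariantTable, VariantTable, list[SiteTruth]]:
    """Simulate matched multi-sample callsets against both versions.

    Both tables describe the same underlying Hardy-Weinberg genotypes with
    independent per-panel missingness and call error; a designated subset of
    sites gets an elevated per-sample error on the B side (expected
    discordant), another subset sits inside duplication sources (expected
    multi-mapped), another has a substituted base inside its flank window
    (expected unmapped), and a low-quality subset is drawn with QUAL/MQ
    below the calling-stage thresholds. Each site's expected fate, given the
    values actually planted, is returned as its truth label.
    """
    params = params or Parameters()
    f = params.flank
    rng = np.random.default_rng(spec.seed)
    names = list(genome_a.contigs)
    lengths = {n: len(genome_a.contigs[n]) for n in names}

    n_multi = round(spec.n_snps * spec.multi_fraction)
    n_unmapped = round(spec.n_snps * spec.unmapped_fraction)
    n_clean = spec.n_snps - n_multi - n_unmapped
    if n_clean <= 0:
        raise ValueError("n_snps too small for the requested subset fractions")

    used: set[tuple[str, int]] = set()

    def sample_clean(count: int) -> list[tuple[str, int, TruthSegment]]:
        out = []
        tries = 0
        while len(out) < count:
            tries += 1
            if tries > 200 * count + 10000:
                raise ValueError("insufficient eligible clean sites")
            ctg = names[int(rng.integers(len(names)))]
            p = int(rng.integers(f, lengths[ctg] - f))
            if (ctg, p) in used:
                continue
            seg = truth.clean_segment(ctg, p - f, p + f + 1)
            if seg is None:
                continue
            used.add((ctg, p))
            out.append((ctg, p, seg))
        return out

    # duplication-source interiors -> expected MULTI
    dup_intervals = sorted({(s.contig_a, s.a_start0, s.a_end0)
                            for s in truth.segments if s.ambiguous})
    multi_sites: list[tuple[str, int, None]] = []
    if n_multi:
        eligible = [iv for iv in dup_intervals if iv[2] - iv[1] > 2 * f + 2]
        if not eligible:
            raise ValueError(
                "no duplication source large enough for the flank window")
        tries = 0
        while len(multi_sites) < n_multi:
            tries += 1
            if tries > 200 * n_multi + 10000:
                raise ValueError("insufficient eligible duplication sites")
            ctg, s, e = eligible[int(rng.integers(len(eligible)))]
            p = int(rng.integers(s + f, e - f))
            if (ctg, p) in used:
                continue
            used.add((ctg, p))
            multi_sites.append((ctg, p, None))

    # windows containing a substituted base -> expected UNMAPPED
    sub_positions = sorted(truth.substitutions)
    unmapped_sites: list[tuple[str, int, None]] = []
    if n_unmapped:
        if not sub_positions:
            raise ValueError("no substitutions available for unmapped sites")
        tries = 0
        while len(unmapped_sites) < n_unmapped:
            tries += 1
            if tries > 500 * n_unmapped + 10000:
                raise ValueError("insufficient eligible unmapped sites")
            ctg, q = sub_positions[int(rng.integers(len(sub_positions)))]
            p = q + int(rng.integers(-f, f + 1))
            if (ctg, p) in used or (ctg, p) in truth.substitutions:
                continue
            if p - f < 0 or p + f >= lengths[ctg]:
                continue
            if truth.clean_segment(ctg, p - f, p + f + 1,
                                   ignore_substitutions=True) is None:
                continue
            used.add((ctg, p))
            unmapped_sites.append((ctg, p, None))

    clean_sites = sample_clean(n_clean)

    n_disc = round(n_clean * spec.discordant_fraction / (1 - spec.multi_fraction
                                                         - spec.unmapped_fraction))
    n_disc = min(n_disc, n_clean)
    n_lowq = min(round(spec.n_snps * spec.lowqual_fraction), n_clean - n_disc)
    special = rng.choice(n_clean, size=n_disc + n_lowq, replace=False)
    disc_idx = set(int(i) for i in special[:n_disc])
    lowq_idx = set(int(i) for i in special[n_disc:])

    samples = tuple(f"acc{i + 1:03d}" for i in range(spec.n_samples))
    sites_a: list[SiteRecord] = []
    sites_b: list[SiteRecord] = []
    truths: list[SiteTruth] = []

    def make_site(ctg: str, p: int, category: str, clean_i: int | None,
                  seg: TruthSegment | None) -> None:
        ref = genome_a.contigs[ctg][p]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        af = rng.uniform(*spec.af_range)
        dosages = _draw_genotypes(rng, af, spec.n_samples)
        lowq = clean_i in lowq_idx if clean_i is not None else False
        disc = clean_i in disc_idx if clean_i is not None else False
        err_b = spec.discordant_error_rate if disc else spec.genotype_error_rate
        gts_a = _panel_calls(rng, dosages, spec.genotype_error_rate,
                             spec.missing_rate)
        if lowq:
            qual_a, mq_a = float(rng.uniform(1, 29)), float(rng.uniform(1, 29))
            qual_b, mq_b = float(rng.uniform(1, 29)), float(rng.uniform(1, 29))
        else:
            qual_a, mq_a = float(rng.uniform(50, 200)), float(rng.uniform(40, 60))
            qual_b, mq_b = float(rng.uniform(50, 200)), float(rng.uniform(40, 60))
        site_a = SiteRecord(ctg, p + 1, ref, alt, qual_a, mq_a, tuple(gts_a))
        sites_a.append(site_a)

        contig_b = pos1_b = strand = None
        pass_both = site_passes_filter(site_a, params)
        if category == "clean":
            assert seg is not None
            pos0_b = seg.project(p)
            strand = seg.strand
            contig_b = seg.contig_b
            pos1_b = pos0_b + 1
            ref_b = complement(ref) if strand == "-" else ref
            alt_b = complement(alt) if strand == "-" else alt
            gts_b = _panel_calls(rng, dosages, err_b, spec.missing_rate)
            site_b = SiteRecord(contig_b, pos1_b, ref_b, alt_b,
                                qual_b, mq_b, tuple(gts_b))
            sites_b.append(site_b)
            pass_both = pass_both and site_passes_filter(site_b, params)

        if not pass_both:
            label = EXPECT_FILTERED
        elif category == "multi":
            label = EXPECT_MULTI
        elif category == "unmapped":
            label = EXPECT_UNMAPPED
        elif disc:
            label = EXPECT_DISCORDANT
        else:
            label = TRANSFERABLE_CONCORDANT
        truths.append(SiteTruth(
            snp_id_a=site_a.snp_id(genome_a.version_tag),
            contig_a=ctg, pos1_a=p + 1,
            contig_b=contig_b, pos1_b=pos1_b, strand=strand, label=label,
        ))

    for ctg, p, _ in multi_sites:
        make_site(ctg, p, "multi", None, None)
    for ctg, p, _ in unmapped_sites:
        make_site(ctg, p, "unmapped", None, None)
    for i, (ctg, p, seg) in enumerate(clean_sites):
        make_site(ctg, p, "clean", i, seg)

    table_a = VariantTable(genome_a.version_tag, samples, sites_a)
    table_b = VariantTable(genome_b.version_tag, samples, sites_b)
    return table_a, table_b, truths


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    precision: float
    recall: float
    confusion: dict[str, dict[str, int]]  # label -> {"total", "kept"}


def evaluate_recovery(
    kept_pairs: Iterable[PairedSnp], truths: Sequence[SiteTruth]
) -> RecoveryReport:
    """Precision/recall of the reliable set against the truth labels.

    Recall is over TRANSFERABLE_CONCORDANT sites; precision is the fraction
    of kept pairs whose A-side site is labeled TRANSFERABLE_CONCORDANT.
    """
    if not truths:
        raise ValueError("empty truth labels")
    kept_keys = {(p.a.contig, p.a.pos1) for p in kept_pairs}
    confusion: dict[str, dict[str, int]] = {}
    for t in truths:
        c = confusion.setdefault(t.label, {"total": 0, "kept": 0})
        c["total"] += 1
        if (t.contig_a, t.pos1_a) in kept_keys:
            c["kept"] += 1
    tc = confusion.get(TRANSFERABLE_CONCORDANT, {"total": 0, "kept": 0})
    recall = tc["kept"] / tc["total"] if tc["total"] else float("nan")
    n_kept = len(kept_keys)
    precision = tc["kept"] / n_kept if n_kept else float("nan")
    return RecoveryReport(precision, recall, confusion)


# ---------------------------------------------------------------------------
# Scenario bundling and truth I/O
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    genome_a: ReferenceAssembly
    genome_b: ReferenceAssembly
    truth: TruthMap
    table_a: VariantTable
    table_b: VariantTable
    truths: list[SiteTruth]
    params: Parameters
    edits: EditSpec
    panel: PanelSpec


def default_scenario(
    seed: int,
    n_contigs: int = 2,
    contig_length: int = 500_000,
    edits: EditSpec | None = None,
    panel: PanelSpec | None = None,
    params: Parameters | None = None,
) -> Scenario:
    """The desk-scale study scenario: two 500-kb contigs, a realistic edit
    burden, and a 60-sample 2000-SNP panel pair."""
    params = params or Parameters(seed=seed)
    edits = edits or EditSpec()
    lengths = {f"chr{i + 1:02d}": contig_length for i in range(n_contigs)}
    genome_a = simulate_reference(lengths, seed, version_tag="simA")
    genome_b, truth = derive_assembly(genome_a, edits, seed + 1,
                                      version_tag="simB")
    panel = panel or PanelSpec(seed=seed + 2)
    table_a, table_b, truths = simulate_panels(genome_a, genome_b, truth,
                                               panel, params)
    return Scenario(genome_a, genome_b, truth, table_a, table_b, truths,
                    params, edits, panel)


def write_truth_tsv(truths: Sequence[SiteTruth], path: str | Path,
                    header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("snp_id\tcontig_a\tpos1_a\tcontig_b\tpos1_b\tstrand\tlabel\n")
        for t in truths:
            fh.write("\t".join(map(str, (
                t.snp_id_a, t.contig_a, t.pos1_a,
                t.contig_b or ".", t.pos1_b or ".", t.strand or ".",
                t.label))) + "\n")


def read_truth_tsv(path: str | Path) -> list[SiteTruth]:
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("snp_id\t"):
                continue
            sid, ca, pa, cb, pb, strand, label = line.split("\t")
            out.append(SiteTruth(
                sid, ca, int(pa),
                None if cb == "." else cb,
                None if pb == "." else int(pb),
                None if strand == "." else strand, label))
    return out


# plain key = value scenario configuration -----------------------------------

_CONFIG_SECTIONS = {"edits": EditSpec, "panel": PanelSpec}


def parse_scenario_config(path: str | Path) -> dict:
    """Parse a plain ``key = value`` scenario config.

    Top-level keys: ``seed`` (mandatory), ``n_contigs``, ``contig_length``,
    and any Parameters field (e.g. ``flank``); prefixed keys configure the
    edit and panel specs (e.g. ``edits.n_inversions = 1``,
    ``panel.n_snps = 200``).
    """
    top: dict[str, str] = {}
    sections: dict[str, dict[str, str]] = {"edits": {}, "panel": {}}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (x.strip() for x in line.split("=", 1))
            if "." in key:
                sect, fieldname = key.split(".", 1)
                if sect not in sections:
                    raise ValueError(f"{path}:{lineno}: unknown section {sect!r}")
                sections[sect][fieldname] = value
            else:
                top[key] = value
    if "seed" not in top:
        raise ValueError(f"{path}: config must set a seed")

    def coerce(cls, raw_fields: dict[str, str], **extra):
        hints = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        kwargs = dict(extra)
        for k, v in raw_fields.items():
            if k not in hints:
                raise ValueError(f"unknown {cls.__name__} field {k!r}")
            current = getattr(cls(**extra) if extra else cls(), k)
            if isinstance(current, tuple):
                kwargs[k] = tuple(type(current[0])(x) for x in v.split(","))
            elif isinstance(current, bool):
                kwargs[k] = v.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[k] = int(v)
            elif isinstance(current, float):
                kwargs[k] = float(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    seed = int(top.pop("seed"))
    n_contigs = int(top.pop("n_contigs", 2))
    contig_length = int(top.pop("contig_length", 500_000))
    param_fields = {f.name for f in Parameters.__dataclass_fields__.values()}
    bad = set(top) - param_fields
    if bad:
        raise ValueError(f"unknown config key(s): {sorted(bad)}")
    params = coerce(Parameters, dict(top), seed=seed)
    edits = coerce(EditSpec, sections["edits"])
    panel = coerce(PanelSpec, sections["panel"], seed=seed + 2)
    return {"seed": seed, "n_contigs": n_contigs,
            "contig_length": contig_length, "params": params,
            "edits": edits, "panel": panel}
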