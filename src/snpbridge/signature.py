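"""Sequence-composition signatures of flanks: k-mer counts, GC content, and
per-feature Welch t-tests between concordant and discordant groups.

k-mer counting is literal and strand-specific (a trinucleotide and its
reverse complement are distinct features), with overlapping windows; windows
touching N are skipped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .flank import FlankRecord
from .reconcile import ConcordanceResult

CONCORDANT = "CONCORDANT"
OTHER = "OTHER"

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order (the count-vector index)."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def kmer_counts(seq: str, k: int = 3) -> np.ndarray:
    """Overlapping literal k-mer counts on the given strand, not canonicalized.

    Returns a vector of length 4^k indexed by lexicographic k-mer; windows
    containing N contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)}")
    counts = np.zeros(4 ** k, dtype=np.int64)
    mask = (1 << (2 * k)) - 1
    val = 0
    run = 0
    for ch in seq:
        c = _BASE_INDEX.get(ch)
        if c is None:
            if ch != "N":
                raise ValueError(f"illegal character {ch!r}")
            val = 0
            run = 0
            continue
        val = ((val << 2) | c) & mask
        run += 1
        if run >= k:
            counts[val] += 1
    return counts


def gc_content(seq: str) -> float:
    """(#G + #C) / (#non-N bases); errors on all-N input."""
    non_n = sum(1 for ch in seq if ch != "N")
    if non_n == 0:
        raise ValueError("GC content undefined for an all-N sequence")
    gc = seq.count("G") + seq.count("C")
    return gc / non_n


@dataclass
class KmerSignature:
    snp_id: str
    counts: np.ndarray
    gc: float
    group: str  # CONCORDANT | OTHER


def build_signatures(
    flanks: Iterable[FlankRecord],
    results: Sequence[ConcordanceResult],
    threshold: float,
    k: int = 3,
) -> list[KmerSignature]:
    """Label each paired flank CONCORDANT (rate >= threshold) or OTHER."""
    rate_by_a_id: dict[str, float] = {}
    for r in results:
        if r.rate is not None:
            a_id = r.pair.id.split("~")[0]
            rate_by_a_id[a_id] = r.rate
    sigs: list[KmerSignature] = []
    for fl in flanks:
        rate = rate_by_a_id.get(fl.snp_id)
        if rate is None:
            continue
        group = CONCORDANT if rate >= threshold else OTHER
        sigs.append(KmerSignature(fl.snp_id, kmer_counts(fl.seq, k),
                                  gc_content(fl.seq), group))
    return sigs


def welch_ttest(x: Sequence[float], y: Sequence[float]
                ) -> tuple[float, float, float, bool]:
    """Welch two-sample t-test: (t, df, p, degenerate).

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), with Welch-Satterthwaite df.
    When both sample variances are zero: equal means give (0, n1+n2-2, 1);
    unequal means are flagged degenerate with p reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0, False
        return math.copysign(math.inf, m1 - m2), float("nan"), 0.0, True
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p, False


def significance_stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def group_compare(
    signatures: Sequence[KmerSignature],
    k: int = 3,
    bonferroni: bool = False,
    extra_features: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Welch t-test per feature (each k-mer count plus GC) between groups.

    ``extra_features`` optionally supplies user-defined numeric features as
    {feature_name: {snp_id: value}} (e.g. a position covariate). With
    ``bonferroni`` the p-values are multiplied by the number of features
    (capped at 1).
    """
    conc = [s for s in signatures if s.group == CONCORDANT]
    other = [s for s in signatures if s.group == OTHER]
    if not conc or not other:
        raise ValueError("both groups must be non-empty")
    if len(conc) < 2 or len(other) < 2:
        raise ValueError("each group needs at least 2 members for a t-test")
    names = all_kmers(k) + ["gc"]
    mat_c = np.column_stack([np.vstack([s.counts for s in conc]),
                             np.array([[s.gc] for s in conc])])
    mat_o = np.column_stack([np.vstack([s.counts for s in other]),
                             np.array([[s.gc] for s in other])])
    columns_c = [mat_c[:, j] for j in range(mat_c.shape[1])]
    columns_o = [mat_o[:, j] for j in range(mat_o.shape[1])]
    if extra_features:
        for fname, values in extra_features.items():
            names.append(fname)
            columns_c.append(np.array([values[s.snp_id] for s in conc]))
            columns_o.append(np.array([values[s.snp_id] for s in other]))
    rows = []
    n_features = len(names)
    for name, xc, xo in zip(names, columns_c, columns_o):
        t, df, p, degenerate = welch_ttest(xc, xo)
        if bonferroni:
            p = min(1.0, p * n_features)
        rows.append({
            "feature": name,
            "mean_concordant": float(np.mean(xc)),
            "mean_other": float(np.mean(xo)),
            "t": t,
            "df": df,
            "p": p,
            "stars": "DEGENERATE" if degenerate else significance_stars(p),
        })
    return pd.DataFrame(rows)


def write_signature_table(df: pd.DataFrame, path: str | Path,
                          header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
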