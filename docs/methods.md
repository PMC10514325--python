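# Methods

This note records the model implemented by `snpbridge`, the assumptions
behind it, the default parameters and why they hold those values, what the
simulator does and does not emulate, and known limitations. It makes no
empirical claims beyond what the test suite and `scripts/acceptance.py`
actually compute.

## Model

Two reference assemblies, A and B, describe the same genome at different
revisions. A variant callset exists against each. The goal is a **reliable
set** of cross-version SNP pairs — sites demonstrably identical in sequence
context and genotype behaviour — which then supports liftover and merging.

### Site identity by flank sequence

A SNP's identity is taken to be its local sequence context: the window of
`2f + 1` bases centred on the site (default `f = 500`, so 1001 bp). Two
sites in different assemblies are candidate partners when this window occurs
**exactly once** in the other assembly, at the partner's position, full
length, with no mismatches, on either strand. Exactness is deliberate:

- a unique exact hit of a 1001-bp probe is essentially impossible by chance
  (a random match has probability ~4^-1001 per position), so a unique hit
  is evidence of true correspondence, not homology;
- repeats show up as multiple hits and are excluded rather than guessed at;
- diverged regions show up as zero hits and are excluded likewise.

The search uses a 2-bit rolling k-mer index of the target
(`k = min(31, 2f + 1)`, k-mers containing N are not indexed) seeded at the
probe's centre, with full-length verification of every candidate; this is
proven equal to a naive both-strand scan by the test suite. Because probes
have odd length, no probe can equal its own reverse complement, so the
strand of a hit is always well defined.

### Reciprocal confirmation

A pair (a, b) is confirmed only if: a's probe maps uniquely onto b's
coordinate; b's probe maps uniquely back onto a's coordinate; both mappings
report the same strand; and the allele set `{REF, ALT}` of b — complemented
when the strand relation is flipped — equals that of a. Every rejected site
is counted under one reason (`UNMAPPED`, `MULTI`, `TARGET_SITE_ABSENT`,
`NOT_RECIPROCAL`, `STRAND_CONFLICT`, `ALLELE_MISMATCH`, `NO_FLANK`), and the
counts add up exactly to the input, so no site leaves the accounting.

### Genotype harmonization and concordance

Genotypes are compared per shared sample as **orientation-free base
multisets**: allele indices are resolved to bases through each record's own
REF/ALT, the B side is complemented once if the pair is strand-flipped, and
the two sorted base pairs are compared. A sample is *informative* when its
call is non-missing in both callsets. A pair's concordance rate is
matches / informative (an option divides by the full shared panel instead),
and the reliable set keeps pairs with rate ≥ the threshold (inclusive).

### Liftover and merging

Liftover re-emits each site of a callset at its partner coordinate with the
partner's REF/ALT, complementing alleles for flipped pairs and re-encoding
genotype indices so every sample's base multiset is preserved exactly —
which makes A→B→A the identity on lifted sites. Merging intersects a native
and a lifted callset by coordinate and allele set, takes the union of
samples (shared accession names kept as two panel-tagged columns, or
collapsed to the less-missing column on request), drops sites whose merged
missing fraction exceeds a cap, and reports a per-site cross-panel genotype
match rate over shared accessions.

### Composition signatures

For quality auditing, each paired flank is summarised by literal overlapping
k-mer counts (default k = 3; not canonicalized, N-containing windows
skipped) and GC content, grouped into concordant versus other, and each
feature is tested with a Welch two-sample t-test (Welch–Satterthwaite
degrees of freedom; optional Bonferroni correction). Degenerate features
(zero variance in both groups) are reported explicitly rather than given a
fabricated p-value.

## Parameters and defaults

| Parameter | Default | Rationale |
| --- | --- | --- |
| `flank` | 500 | 1001-bp probe: long enough that an exact unique hit is conclusive, short enough to survive typical inter-version divergence. |
| `min_qual` | 30 | Strict `QUAL > 30`: standard Phred threshold for a confident variant call. |
| `min_mq` | 30 | Strict `MQ > 30` on the site-level INFO/MQ field; records without MQ fail (missing evidence is not evidence). |
| `min_maf` | 0.02 | Strict `MAF > 0.02` over non-missing allele calls; removes singleton-like artefacts in panels of tens of samples. |
| `max_missing_call` | 0.05 | Strict missing `< 0.05`; heavily missing sites make concordance unstable. |
| `concordance_threshold` | 0.90 | Inclusive `rate ≥ 0.90`; tolerates a few per-sample genotyping errors while excluding genuinely discordant sites with overwhelming probability (binomial tails, verified in the acceptance suite). |
| `min_informative` | 1 | Below this many informative samples the rate is reported as undefined (NA) rather than 0 or 1. |
| `kmer_k` | 3 | Trinucleotide signatures: 64 features, interpretable and well-populated at 1001 bp. |
| `merge_max_missing` | 0.05 | Same strictness as the per-callset filter, applied to the merged matrix. |

## The simulator

The simulator exists to provide **ground truth**: every generated SNP site
carries a label describing its expected fate, so precision and recall of the
reliable set are measurable.

What it emulates:

- a base assembly of i.i.d. uniform A/C/G/T contigs (default: 2 × 500 kb);
- a derived assembly produced by tracked, non-overlapping edits — point
  substitutions (0.05%), small insertions and deletions (1–10 bp, 10 each),
  inversions (3, 1–10 kb), tandem duplications (3, 2–5 kb), one
  translocation, and N-gaps (2, 200–500 bp) — with an exact piecewise
  interval map (the `TruthMap`) between the two;
- matched genotype panels (60 samples, 2000 SNPs): allele frequencies drawn
  from 0.05–0.5, Hardy–Weinberg genotypes shared between panels, 2%
  missingness and 0.5% genotype error per panel, a 2% subset with 50%
  genotype error on the B side (planted discordance), a 2.5% subset placed
  inside duplication sources (expected multi-mapping), a 5% subset whose
  flanks overlap edits (expected unmapped), and a 5% low-quality subset
  (QUAL/MQ drawn below the filter thresholds);
- truth labels `TRANSFERABLE_CONCORDANT`, `EXPECT_MULTI`, `EXPECT_UNMAPPED`,
  `EXPECT_DISCORDANT`, and `EXPECT_FILTERED` (sites whose planted
  QUAL/MQ/MAF/missingness deterministically fail the strict filter; the
  generator applies the same criteria it plants, so the label is ground
  truth rather than a peek at the pipeline).

What it does **not** emulate: real genome composition (repeat families, GC
heterogeneity, transposons), read-level sequencing (no reads, aligners or
callers are simulated — QUAL/MQ are planted numbers), linkage
disequilibrium or population structure, polyploidy, and multi-allelic or
indel variation. Conclusions about real-data yield cannot be read off the
simulator; it validates the machinery, not the biology.

## Numerical and design choices

- **Determinism.** All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived seeds stay below 2^31. Repeated runs
  are byte-identical (tested).
- **Exact integer accounting.** Concordance is kept as `(n_informative,
  n_match)` integer pairs; rates are derived at presentation time (6 decimal
  places in TSV, `NA` for undefined). Filter and pairing reports conserve
  their inputs exactly.
- **Strictness at boundaries.** All filter comparisons are strict
  (`QUAL = 30`, `MQ = 30`, `MAF = 0.02`, missing `= 0.05` are rejected);
  the concordance threshold is inclusive (`rate = 0.90` is kept). Both are
  pinned by tests.
- **Welch, not pooled, t.** Group sizes and variances between concordant
  and other groups are typically unequal, so the pooled-variance test would
  be miscalibrated; type-I error of the Welch implementation is verified at
  0.05 ± 0.02 on null simulations.
- **Site-level MQ.** The mapping-quality filter reads the INFO/MQ field
  (RMS mapping quality of the site), not per-read values, which a VCF does
  not carry; absent MQ loads as NaN and fails the strict comparison.
- **Strand-flip invariance.** The invariance the pipeline guarantees is
  under reverse-complementing each contig of B (with coordinates remapped
  `pos' = L - pos + 1` and B's REF/ALT complemented): every pair's
  informative/match counts are unchanged. A base-wise complement without
  reversal is not an orientation change of an assembly and destroys exact
  matching; no tool property can or should survive it.

## Limitations

- Exact full-length matching is conservative by construction: any edit
  within 500 bp of a site (including a single substitution) makes it
  unmapped. On real assemblies with appreciable divergence, yield will be
  lower than on the simulator; the remedy (shorter flanks) trades
  uniqueness for sensitivity and is exposed via `--flank`.
- The k-mer index holds all positions of the target in memory
  (~a few hundred MB per Gb of genome); desk-scale and crop-genome scale
  are fine on a workstation, but nothing is memory-mapped or disk-backed.
- Only biallelic SNPs are handled; indels and multi-allelic records are
  skipped on input (with a logged count).
- Concordance requires shared sample names between callsets; there is no
  fuzzy accession matching.
- The known-sites VCF export is minimal (sample-free, no INFO annotations)
  and intended as a recalibration input, not an archival callset.
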