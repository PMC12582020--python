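# Methods

## Reference model

The alignment reference is built from mature tRNA sequences, not genomic
loci. Gene records (FASTA + tab-delimited annotation: gene id, isotype,
anticodon, optional per-base Sprinzl labels) are collapsed by exact
sequence identity; the representative id of a collapsed group is the
lexicographically smallest member gene id so the reference is stable
across runs. Sequences are held in the DNA alphabet (U → T on read),
matching the DNA-space reference the aligner consumes, and the 3′ CCA
status of inputs is taken as given — no CCA appending is performed, since
library adapters ligate to the existing NCCA overhang. Each unique
sequence is padded with the 5′/3′ adapter context used in library
construction; the shipped defaults are synthetic stand-ins, and real
libraries should configure their own oligos. Sprinzl labels are input
data (curated annotation), never inferred: the package only validates
injectivity per sequence and the anticodon at labels 34–36, and exposes
the bidirectional position↔label map. All internal coordinates are
0-based half-open; SAM (1-based) and bedMethyl (0-based) conventions are
converted at the I/O boundary by pysam and the bedMethyl parser.

## MOD-MAPQ and read classification

A short, low-diversity reference makes the aligner's MAPQ uninformative:
co-considered alternatives within 80 % of the primary score drive MAPQ to
0 even when the primary is strictly best. The recalibrated quality is

    d = AS_primary − max(AS_alternatives)
    MOD-MAPQ = max(MAPQ, d) if d > 0 else MAPQ

capped at 60 (downstream tools assume the conventional ceiling) and equal
to the original MAPQ when no scored alternatives exist. Alternatives are
secondary alignment records carrying `AS` tags; secondaries without `AS`
are dropped with a logged count (the XA string is not scored — it carries
no alignment score). Classification then partitions reads: unmapped;
antisense (reverse-strand primary, a proxy for mis-mapping); unique
(MOD-MAPQ ≥ 1); and for MOD-MAPQ 0 the *equal-top-score set* — all hits
whose raw `AS` equals the primary's — decides `same_target` (one
reference sequence), `same_codon` (one anticodon) or `ambiguous`. Strict
raw-score equality is used; tie-breaking on recalibrated values would be
circular.

## Quantification

Counting uses forward-strand reads with mean base-call quality strictly
above 4.0 (threshold configurable; an alternative MAPQ ≥ 1 reading of the
filter is expressible because unique-category reads have MOD-MAPQ ≥ 1 by
construction). QC counts are kept per (anticodon, MOD-MAPQ, category).
The expression matrix sums MAPQ > 0 unique reads plus the MAPQ-0
`same_codon` rescue; `same_target` reads also identify a single
anticodon and are included by default, with `include_same_target=False`
giving the stricter variant. Ambiguous reads are binned for QC under
their primary hit's anticodon but never counted. Columns are scaled to a
fixed sum of 1000; normalization requires a nonzero column and is
scale-invariant. Anticodon labels are `Isotype-ANTICODON` in DNA space
(e.g. `Arg-TCT`). Differential expression is out of scope: raw count
matrices are exported for external count-based tools.

## Error profiles

Per-position pileups count sequencing events — matches, mismatches and
deletions — from primary records with recalibrated MAPQ ≥ 1 and base
quality ≥ 2; deletions carry no base quality and always count, at every
deleted reference position. Insertions are attributed to the position
left of the insertion and tracked but excluded from events. Depth is
capped at 50 000 per position, first-come in file order, so reruns are
identical. Counting is implemented over pysam-fetched aligned pairs
rather than the htslib pileup engine because these conventions (deletion
counting irrespective of base quality, left-attributed insertions,
deterministic cap) are not all expressible through the engine's filters.

Per position, `relative_error = (mismatch + deletion) / events` and
`ref_base_fraction = ref / events`; they sum to 1 exactly (same
denominator, complementary numerators). Deletions are included in the
"incorrect calls" numerator, switchable via `include_deletions`.
Positions with fewer than 80 events are excluded everywhere downstream.
Condition ratios `log2(mean_exp / mean_ctrl)` are computed only on
positions passing the event filter in *every* replicate of both
conditions (intersection), avoiding replicate-composition artifacts; a
zero control mean yields an infinity sentinel, with an optional
pseudo-count for plotting only. The global screen averages replicates per
(tRNA, position), groups by Sprinzl label, and applies a two-sample
t-test per label — Welch by default (the safer choice under unequal
variances; a pooled variant is available) — with Benjamini–Hochberg
correction across labels. All labels present in both conditions with ≥ 2
observations per group are tested. The Welch statistic and BH adjustment
are small closed forms implemented in-package (degrees of freedom via a
normalized Satterthwaite formula that does not underflow for denormal
variances; degenerate zero-variance groups defined as t=0, p=1 for equal
means); scipy and statsmodels serve as independent cross-checks in the
tests, agreeing to < 1e-10 on shared inputs.

## Modification pileups

bedMethyl records (modkit dialect: BED9 + space-separated count block;
codes m = m5C, a = m6A, 17802 = Ψ) are validated against their own counts
and filtered to plus-strand records whose reference base equals the
modification's unmodified base with ≥ 100 valid calls. Fractions are
stored as [0,1] and rendered as percent at I/O; cutoffs are accepted in
percent and applied strictly (`> 10 %` excludes exactly 10 %). Per-site
probabilities are unweighted means over an explicit untreated sample set
taken from the sample sheet, never inferred from file names; samples
lacking a site contribute no term. Cross-method comparison keys sites on
(tRNA identifier, Sprinzl label), by default after anticodon roll-up
taking the maximum mean probability across isodecoders (a family counts
as modified if any member is), with per-isodecoder keying available; the
orthogonal table is pre-filtered at a configurable rate (0 for
m5C-bisulfite style inputs, > 10 % for high-confidence Ψ sets), and
orthogonal rows naming unknown tRNAs are reported as unmapped rather
than dropped. Isomer confounds of the underlying caller (m1A at 58
reported as m6A; m3C at 32 as m5C) are documented caveats — no
correction is attempted.

## Simulator: what it emulates, and what it does not

The generator's defaults are the study conditions under which the package
is validated: 6 anticodons × 2 isodecoders (1 nt apart) × 2 exact gene
copies (24 genes → 12 uniques), two replicates per condition with
negative-binomial depth around 5000 reads, fixed decreasing isoacceptor
abundances, 5 % antisense reads, 5 % low-quality reads, 5 % / 5 % / 3 %
planted same-target / same-codon / ambiguous multi-mapping, a 5 %
per-position baseline error rate (typical of direct-RNA base-calling)
split 70/30 between mismatches and deletions, a 4× error spike at
Sprinzl 37 in the experimental condition (a TYW2-style contrast), and
binomial modification pileups at the conserved m5C-48 and Ψ-55 positions
(fractions 0.80 / 0.90, depth ~1000) plus deliberate filter traps
(minus-strand, 50-valid-call, reference-mismatch records). Alignment
scores use match +1 / edit −2 — only score differences matter to
MOD-MAPQ — and same-codon reads are made genuinely co-optimal by deleting
the bases that distinguish the isodecoder pair. All randomness flows from
one seed; identical seeds give byte-identical files.

Deliberately not modelled: raw current signal, sequence-context error
profiles, homopolymer effects, truncated reads, and cross-talk between
neighbouring modified positions. Passing tests therefore demonstrate the
correctness of the *logic* (recalibration, classification, counting,
filtering, statistics) under known truth, not base-caller accuracy on
real data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: reference
widths of 2–12 unique sequences, 3000–12 000 reads per sample, 10⁵
randomized pileups for the error identity, 200 random group pairs for
the statistics cross-check and 100 all-null runs for FDR control; the
planted-spike contrast uses ~5000× per-position depth so the binomial
error of the log2 ratio is well inside ±0.1. The global per-label test
is evaluated on the full-width reference (12 tRNAs per group), since
with only two tRNAs per label a t-test has one effective degree of
freedom and no resolving power — depth cannot substitute for breadth
there. Ties in BH adjustment are handled by the standard step-up with a
monotone cap; mergesort keeps the permutation stable.

## Known limitations

* Sprinzl annotation is consumed, not computed; tRNAs lacking labels are
  silently absent from label-keyed outputs.
* The XA-style alternative-hit dialect is ignored (no scores), so input
  must come from an aligner run in report-all/secondary mode.
* The equal-top-score rule uses exact integer score equality; aligners
  emitting near-ties under floating-point scoring would need a tolerance.
* The per-position depth cap keeps the *first* reads in file order;
  coordinate-sorted and name-sorted inputs can therefore differ in the
  capped tail beyond 50 000×.
* Antisense reads are excluded from counting but not from pileups;
  heavily antisense-contaminated samples will dilute error profiles.
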