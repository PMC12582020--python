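# nanotrna

Post-processing for nanopore direct tRNA sequencing: reference curation,
mapping-quality recalibration, anticodon-level quantification, and
modification inference from base-calling errors and modification pileups.

## The problem

Mature human tRNAs are short (~76 nt), heavily modified, and encoded by
hundreds of near-redundant genes — the hg19 tRNA gene set collapses from
414 genes to 267 unique sequences over 47 isoacceptors, with isodecoders
differing by as little as one nucleotide. Aligning direct-RNA nanopore
reads against such a reference leaves a large share of reads at MAPQ 0
even when their primary alignment is strictly best, and modifications
produce systematic base-calling errors that are signal, not noise. This
package implements the analysis stack that deals with both:

* **Reference curation** — collapse a gene set to unique sequences
  (deterministic representative ids, member bookkeeping), pad with the
  library adapter context, and attach Sprinzl position labels
  (the canonical tRNA coordinate system) from the annotation table.
* **MOD-MAPQ recalibration** — for each read, compute
  `d = AS_primary − AS_best_alt` from the aligner's score tags; if
  `d > 0` and exceeds the reported MAPQ, the MAPQ becomes `d` (capped at
  60). MAPQ-0 reads whose co-optimal hits all point at one reference
  sequence ("same target") or one anticodon ("same codon") are rescued;
  reverse-strand primaries are antisense (a mis-mapping proxy).
* **Quantification** — per-anticodon counts binned by recalibrated MAPQ
  and category; the expression matrix sums MAPQ > 0 reads plus the MAPQ-0
  rescues, and columns are normalized to a fixed sum of 1000. Reads need
  mean base-call quality > 4.0 to be counted.
* **Error profiling** — per-position event counts (match / mismatch /
  deletion; insertions tracked but excluded) from reads with recalibrated
  MAPQ ≥ 1 and base quality ≥ 2, with a deterministic 50 000 depth cap.
  `relative_error = (mismatch + deletion) / events` and
  `ref_base_fraction = ref_count / events` sum to one. Positions with
  < 80 events are excluded. Condition contrasts use
  `log2(mean_exp / mean_ctrl)`, and a global per-Sprinzl-label screen runs
  Welch t-tests over per-tRNA error rates with Benjamini–Hochberg
  correction.
* **Modification pileups** — parse modkit-dialect bedMethyl, keep
  plus-strand records whose reference base matches the unmodified base
  with ≥ 100 valid calls, average the modified fraction over untreated
  samples, threshold at > 0 / 10 / 20 %, and compare site sets against
  orthogonal chemical methods keyed on (tRNA, Sprinzl label).
* **Simulator** — generates all of the above inputs (duplicate gene
  copies, 1-nt-apart isodecoders, co-optimal multi-mapping, planted error
  spikes, antisense contamination, binomial modification pileups) with
  truth tables, fully determined by one seed.

## Worked example

Simulate a two-condition dataset and run the whole pipeline:

```sh
nanotrna sim --seed 4 --out-dir simdata
# -> 24 genes, 12 uniques, 6 anticodons -> simdata

nanotrna ref --fasta simdata/genes.fasta --annot simdata/genes.tsv \
    --adapter5 CCTGTACTTCGTTCAG --adapter3 GGCTTCTTCTTGCTCT --out-dir ref
# -> 24 genes -> 12 unique sequences, 6 isoacceptors

nanotrna recal --bam-in simdata/ctrl1.sam --uniques ref/uniques.tsv \
    --bam-out ctrl1.recal.sam --assignments-out ctrl1.assignments.tsv
# -> unique       4091
#    same_target    254
#    antisense      248
#    same_codon     227
#    ambiguous      158
```

The category counts say what happened to every read: most are uniquely
assignable after recalibration, ~5 % map antisense, and the MAPQ-0
rescues (`same_target`, `same_codon`) recover reads that a naive MAPQ
filter would discard. `quant`, `errors` and `mods` then produce the
fixed-sum expression matrix, the per-position error tables (with the
per-Sprinzl-position test results) and the thresholded modification site
sets; `nanotrna run --config run.yaml --out-dir out` chains all stages
and writes a manifest with every threshold and output checksum.

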