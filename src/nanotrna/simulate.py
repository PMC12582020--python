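"""Seeded synthetic data with ground truth for the whole pipeline.

The simulator emits every input the pipeline consumes — a tRNA gene set
with exact duplicate gene copies and near-identical (≥1 nt apart)
isodecoders, aligned reads with co-optimal multi-mapping hits, planted
per-position error spikes, antisense contamination and replicate noise,
and bedMethyl pileups with known modified fractions — together with truth
tables, so every module can be tested at desk scale without downloads.

Reads are emitted as already-aligned SAM records (the pipeline's contract
starts at the aligned BAM); alignment scores use a simple linear scheme
(match +1, mismatch/deleted base −2) documented in the SAM header — only
score *differences* matter downstream. All randomness flows from the
config seed; the same seed yields byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from nanotrna.alignment import Category
from nanotrna.modsites import MOD_CODE_CANONICAL, ModPileupRecord, write_bedmethyl
from nanotrna.reference import (
    PaddedReference,
    SprinzlAnnotation,
    TRNAGeneRecord,
    UniqueTRNA,
    build_padded_reference,
    deduplicate,
    load_sprinzl,
    write_fasta,
)

_BASES = np.array(list("ACGT"))

# Anticodons used round-robin for synthetic references; chosen to cover
# common human isoacceptors (Gly-GCC, Asp-GTC, Ser-GCT, Phe-GAA, Arg-TCT...).
_ANTICODON_POOL = [
    "GCC", "GTC", "GCT", "GAA", "TCT", "CAT",
    "GCA", "TAA", "CAG", "AAC", "TTC", "TTT",
    "CCA", "GTG", "AGT", "ACG", "CTG", "TGC",
]

MATCH_SCORE = 1
EDIT_PENALTY = 2


def _isotype_of(anticodon: str) -> str:
    codon = str(Seq(anticodon).reverse_complement())
    aa = str(Seq(codon).translate())
    return "Sup" if aa == "*" else seq3(aa)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe a desk-scale TYW2-like two-condition experiment:
    a modest reference with planted duplicate gene copies and 1-nt-apart
    isodecoders, two replicates per condition, a few percent of antisense
    and multi-mapping reads, a 5% baseline error rate (typical of direct
    RNA base-calling) with a 4× spike at Sprinzl 37 in the experimental
    condition, and modification pileups at the conserved m5C 48 / Ψ 55
    positions.
    """

    seed: int = 0
    n_anticodons: int = 6
    isodecoders_per_anticodon: int = 2
    duplicate_gene_copies: int = 2
    body_length: int = 72
    adapter5: str = "CCTGTACTTCGTTCAG"   # synthetic stand-ins for the
    adapter3: str = "GGCTTCTTCTTGCTCT"   # library adapter context
    n_replicates: int = 2
    reads_per_sample: int = 5000
    dispersion: float = 20.0  # negative-binomial size for replicate depth
    antisense_rate: float = 0.05
    low_quality_rate: float = 0.05
    same_target_rate: float = 0.05
    same_codon_rate: float = 0.05
    ambiguous_rate: float = 0.03
    unique_alt_rate: float = 0.5  # unique reads carrying a lower-score alt
    baseline_error_rate: float = 0.05
    # (anticodon label or "*", Sprinzl label, error multiplier) applied in
    # the experimental condition only
    error_spikes: tuple[tuple[str, str, float], ...] = (("*", "37", 4.0),)
    # (anticodon label or "*", Sprinzl label, mod code, true fraction)
    mod_sites: tuple[tuple[str, str, str, float], ...] = (
        ("*", "48", "m", 0.80),
        ("*", "55", "17802", 0.90),
    )
    mod_depth: int = 1000
    mod_background_fraction: float = 0.002
    include_filter_traps: bool = True  # minus-strand / low-valid records
    expression_proportions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for rate in (
            self.antisense_rate,
            self.low_quality_rate,
            self.same_target_rate,
            self.same_codon_rate,
            self.ambiguous_rate,
            self.baseline_error_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.n_anticodons > len(_ANTICODON_POOL):
            raise ValueError(
                f"at most {len(_ANTICODON_POOL)} anticodons supported"
            )
        if self.expression_proportions is not None:
            total = sum(self.expression_proportions)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("expression proportions must sum to 1")


@dataclass
class TruthTables:
    """Ground truth recorded while simulating."""

    n_genes: int
    n_uniques: int
    n_anticodons: int
    unique_members: dict[str, tuple[str, ...]]
    expression_proportions: dict[str, float]  # per unique seq_id
    anticodon_proportions: dict[str, float]
    error_rates: pd.DataFrame | None = None
    read_truth: pd.DataFrame | None = None
    mod_truth: pd.DataFrame | None = None


class Simulator:
    """Generates the full synthetic dataset for one configuration."""

    def __init__(self, config: SimulationConfig) -> None:
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        (
            self._ss_ref,
            self._ss_reads,
            self._ss_mods,
        ) = ss.spawn(3)
        self.genes: list[TRNAGeneRecord] = []
        self.uniques: list[UniqueTRNA] = []
        self.padded: list[PaddedReference] = []
        self.sprinzl: dict[str, SprinzlAnnotation] = {}
        self._siblings: dict[str, list[tuple[str, list[int]]]] = {}
        self.truth: TruthTables | None = None
        self._build_reference()

    # -- reference ---------------------------------------------------------

    def _build_reference(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(self._ss_ref)
        genes: list[TRNAGeneRecord] = []
        bodies: dict[str, str] = {}
        labels = tuple(str(i + 1) for i in range(cfg.body_length))
        # positions reserved from isodecoder mutation: anticodon 34-36,
        # conserved 48 (C) and 55 (T), the 3' CCA
        reserved = {33, 34, 35, 47, 54} | {
            cfg.body_length - 3, cfg.body_length - 2, cfg.body_length - 1
        }
        for ai in range(cfg.n_anticodons):
            anticodon = _ANTICODON_POOL[ai]
            isotype = _isotype_of(anticodon)
            base = rng.choice(_BASES, size=cfg.body_length)
            base[33:36] = list(anticodon)
            base[47] = "C"
            base[54] = "T"
            base[-3:] = list("CCA")
            iso_bodies: list[tuple[str, list[int]]] = []
            for iso in range(cfg.isodecoders_per_anticodon):
                body = base.copy()
                mut_positions: list[int] = []
                if iso > 0:
                    pos = 9 + iso
                    while pos in reserved:
                        pos += 1
                    others = [b for b in "ACGT" if b != body[pos]]
                    body[pos] = others[int(rng.integers(len(others)))]
                    mut_positions.append(pos)
                seq = "".join(body)
                first_gene = f"tRNA-{isotype}-{anticodon}-{iso + 1}-1"
                iso_bodies.append((first_gene, mut_positions))
                bodies[first_gene] = seq
                for copy in range(cfg.duplicate_gene_copies):
                    genes.append(
                        TRNAGeneRecord(
                            gene_id=f"tRNA-{isotype}-{anticodon}-{iso + 1}-{copy + 1}",
                            sequence=seq,
                            isotype=isotype,
                            anticodon=anticodon,
                            sprinzl_labels=labels,
                        )
                    )
            # sibling map: for each isodecoder, the other isodecoders of the
            # same anticodon and the body positions distinguishing them
            for gid, muts in iso_bodies:
                sibs = []
                for gid2, muts2 in iso_bodies:
                    if gid2 == gid:
                        continue
                    diff = sorted(set(muts) ^ set(muts2))
                    sibs.append((gid2, diff))
                self._siblings[gid] = sibs

        self.genes = genes
        self.uniques = deduplicate(genes)
        self.padded = build_padded_reference(
            self.uniques, cfg.adapter5, cfg.adapter3
        )
        self.sprinzl = load_sprinzl(genes, self.uniques)

        if cfg.expression_proportions is not None:
            props = np.asarray(cfg.expression_proportions, dtype=float)
            if len(props) != len(self.uniques):
                raise ValueError(
                    f"{len(props)} proportions for {len(self.uniques)} uniques"
                )
        else:
            # fixed decreasing weights: realistic spread of isoacceptor
            # abundances, deterministic regardless of seed
            props = 2.0 ** (-np.arange(len(self.uniques)) / 3.0)
            props /= props.sum()
        self._proportions = props

        anticodon_props: dict[str, float] = {}
        for u, p in zip(self.uniques, props):
            anticodon_props[u.anticodon_label] = (
                anticodon_props.get(u.anticodon_label, 0.0) + float(p)
            )
        self.truth = TruthTables(
            n_genes=len(genes),
            n_uniques=len(self.uniques),
            n_anticodons=len({u.anticodon_label for u in self.uniques}),
            unique_members={u.seq_id: u.member_gene_ids for u in self.uniques},
            expression_proportions={
                u.seq_id: float(p) for u, p in zip(self.uniques, props)
            },
            anticodon_proportions=anticodon_props,
            error_rates=self._true_error_rates(),
        )

    def _spike_multiplier(self, unique: UniqueTRNA, body_pos: int) -> float:
        mult = 1.0
        ann = self.sprinzl[unique.seq_id]
        for spec, label, m in self.config.error_spikes:
            if spec not in ("*", unique.anticodon_label, unique.seq_id):
                continue
            if ann.linear_of(label) == body_pos:
                mult *= m
        return mult

    def _true_error_rates(self) -> pd.DataFrame:
        rows = []
        for u in self.uniques:
            for pos in range(len(u.sequence)):
                mult = self._spike_multiplier(u, pos)
                base = self.config.baseline_error_rate
                rows.append(
                    {
                        "seq_id": u.seq_id,
                        "position": pos,
                        "ctrl_error_rate": base,
                        "exp_error_rate": min(base * mult, 0.95),
                        "spiked": mult > 1.0,
                    }
                )
        return pd.DataFrame(rows)

    # -- reads -------------------------------------------------------------

    def _sam_header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [
                    {"SN": p.seq_id, "LN": len(p.padded_sequence)}
                    for p in self.padded
                ],
                "CO": [
                    "synthetic reads; AS = matches*"
                    f"{MATCH_SCORE} - edits*{EDIT_PENALTY}"
                ],
            }
        )

    def simulate_alignments(
        self,
        sam_path: str | Path,
        sample_id: str,
        with_spikes: bool = False,
        n_reads: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> pd.DataFrame:
        """Write one sample's aligned SAM; returns the per-read truth table."""
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(
                [cfg.seed, zlib.crc32(sample_id.encode())]
            )
        if n_reads is None:
            # negative-binomial depth dispersion across replicates
            p = cfg.dispersion / (cfg.dispersion + cfg.reads_per_sample)
            n_reads = int(rng.negative_binomial(cfg.dispersion, p))
        by_id = {u.seq_id: u for u in self.uniques}
        pad5 = {p.seq_id: p.pad5_len for p in self.padded}
        header = self._sam_header()
        tid = {p.seq_id: i for i, p in enumerate(self.padded)}
        anticodon_uniques: dict[str, list[str]] = {}
        for u in self.uniques:
            anticodon_uniques.setdefault(u.anticodon_label, []).append(u.seq_id)

        source_idx = rng.choice(
            len(self.uniques), size=n_reads, p=self._proportions
        )
        truth_rows = []
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
            for i in range(n_reads):
                u = self.uniques[int(source_idx[i])]
                read_id = f"{sample_id}_read{i:06d}"
                r = rng.random()
                siblings = self._siblings.get(u.seq_id, [])
                category = Category.UNIQUE
                if r < cfg.antisense_rate:
                    category = Category.ANTISENSE
                elif r < cfg.antisense_rate + cfg.same_target_rate:
                    category = Category.SAME_TARGET
                elif (
                    r
                    < cfg.antisense_rate
                    + cfg.same_target_rate
                    + cfg.same_codon_rate
                    and siblings
                ):
                    category = Category.SAME_CODON
                elif (
                    r
                    < cfg.antisense_rate
                    + cfg.same_target_rate
                    + cfg.same_codon_rate
                    + cfg.ambiguous_rate
                    and len(anticodon_uniques) > 1
                ):
                    category = Category.AMBIGUOUS

                low_q = rng.random() < cfg.low_quality_rate
                qual = 3 if low_q else int(np.clip(rng.normal(12, 2), 5, 30))

                forced_dels: set[int] = set()
                sibling_id: str | None = None
                if category is Category.SAME_CODON:
                    sibling_id, diff = siblings[
                        int(rng.integers(len(siblings)))
                    ]
                    forced_dels = set(diff)

                seq, cigar, n_matches, n_edits = self._mutate_read(
                    u, rng, with_spikes, forced_dels
                )
                a = pysam.AlignedSegment(header)
                a.query_name = read_id
                a.reference_id = tid[u.seq_id]
                a.reference_start = pad5[u.seq_id]
                a.mapping_quality = 60
                primary_as = n_matches * MATCH_SCORE - n_edits * EDIT_PENALTY
                alt: tuple[str, int] | None = None
                if category is Category.ANTISENSE:
                    a.flag = 16
                    seq = u.sequence  # perfect reverse-strand alignment
                    cigar = [(0, len(seq))]
                    primary_as = len(seq) * MATCH_SCORE
                elif category is Category.SAME_TARGET:
                    a.mapping_quality = 0
                    alt = (u.seq_id, primary_as)
                elif category is Category.SAME_CODON:
                    a.mapping_quality = 0
                    alt = (sibling_id, primary_as)  # type: ignore[arg-type]
                elif category is Category.AMBIGUOUS:
                    a.mapping_quality = 0
                    other_labels = [
                        lab
                        for lab in anticodon_uniques
                        if lab != u.anticodon_label
                    ]
                    lab = other_labels[int(rng.integers(len(other_labels)))]
                    choices = anticodon_uniques[lab]
                    alt = (
                        choices[int(rng.integers(len(choices)))],
                        primary_as,
                    )
                elif rng.random() < cfg.unique_alt_rate and len(self.uniques) > 1:
                    # unique read rescued from mapq 0 by the score gap
                    a.mapping_quality = 0
                    gap = int(rng.integers(1, 9))
                    others = [
                        s for s in by_id if s != u.seq_id
                    ]
                    alt = (
                        others[int(rng.integers(len(others)))],
                        primary_as - gap,
                    )
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(
                    chr(qual + 33) * len(seq)
                )
                a.cigartuples = cigar
                a.set_tag("AS", primary_as)
                # pass-through base-modification tags
                a.set_tag("MM", "C+m?;", value_type="Z")
                out.write(a)
                if alt is not None:
                    s = pysam.AlignedSegment(header)
                    s.query_name = read_id
                    s.flag = 256
                    s.reference_id = tid[alt[0]]
                    s.reference_start = pad5[alt[0]]
                    s.mapping_quality = 0
                    s.query_sequence = seq
                    s.cigartuples = cigar
                    s.set_tag("AS", alt[1])
                    out.write(s)
                truth_rows.append(
                    {
                        "sample": sample_id,
                        "read_id": read_id,
                        "seq_id": u.seq_id,
                        "anticodon": u.anticodon_label,
                        "category": category.value,
                        "mean_quality": float(qual),
                        "quality_pass": qual > 4.0,
                    }
                )
        return pd.DataFrame(truth_rows)

    def _mutate_read(
        self,
        unique: UniqueTRNA,
        rng: np.random.Generator,
        with_spikes: bool,
        forced_dels: set[int],
    ) -> tuple[str, list[tuple[int, int]], int, int]:
        """Apply per-position errors to a full-length body read.

        Returns (query sequence, cigartuples, n_matches, n_edits); an error
        is a mismatch with probability 0.7, else a deletion.
        """
        cfg = self.config
        seq_chars: list[str] = []
        ops: list[int] = []  # 0 = M, 2 = D per position
        n_matches = n_edits = 0
        body = unique.sequence
        for pos, ref_base in enumerate(body):
            if pos in forced_dels:
                ops.append(2)
                n_edits += 1
                continue
            rate = cfg.baseline_error_rate
            if with_spikes:
                rate = min(rate * self._spike_multiplier(unique, pos), 0.95)
            if rng.random() < rate:
                n_edits += 1
                if rng.random() < 0.7:
                    others = [b for b in "ACGT" if b != ref_base]
                    seq_chars.append(
                        others[int(rng.integers(3))]
                    )
                    ops.append(0)
                else:
                    ops.append(2)
            else:
                seq_chars.append(ref_base)
                ops.append(0)
                n_matches += 1
        cigar: list[tuple[int, int]] = []
        for op in ops:
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + 1)
            else:
                cigar.append((op, 1))
        return "".join(seq_chars), cigar, n_matches, n_edits

    # -- bedMethyl ---------------------------------------------------------

    def simulate_modkit_pileup(
        self,
        out_path: str | Path,
        sample_id: str,
        rng: np.random.Generator | None = None,
    ) -> pd.DataFrame:
        """Write one sample's bedMethyl pileup; returns the site truth table."""
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(
                [cfg.seed, 1, zlib.crc32(sample_id.encode())]
            )
        pad5 = {p.seq_id: p.pad5_len for p in self.padded}
        records: list[ModPileupRecord] = []
        truth_rows = []

        def emit(seq_id, padded_pos, code, fraction, strand="+", depth=None):
            n_valid = (
                int(rng.poisson(cfg.mod_depth)) if depth is None else depth
            )
            n_valid = max(n_valid, 1)
            n_mod = int(rng.binomial(n_valid, fraction))
            records.append(
                ModPileupRecord(
                    seq_id=seq_id,
                    position=padded_pos,
                    strand=strand,
                    mod_code=code,
                    n_valid=n_valid,
                    n_mod=n_mod,
                    n_canonical=n_valid - n_mod,
                )
            )
            truth_rows.append(
                {
                    "sample": sample_id,
                    "seq_id": seq_id,
                    "position": padded_pos,
                    "mod_code": code,
                    "true_fraction": fraction,
                    "n_valid": n_valid,
                    "strand": strand,
                }
            )

        for u in self.uniques:
            ann = self.sprinzl[u.seq_id]
            offset = pad5[u.seq_id]
            for spec, label, code, fraction in cfg.mod_sites:
                if spec not in ("*", u.anticodon_label, u.seq_id):
                    continue
                pos = ann.linear_of(label)
                if pos is None:
                    continue
                if u.sequence[pos] != MOD_CODE_CANONICAL[code]:
                    continue
                emit(u.seq_id, offset + pos, code, fraction)
            # background: first two canonical-C body positions not planted
            planted = {r["position"] for r in truth_rows if r["seq_id"] == u.seq_id}
            background = [
                i
                for i, b in enumerate(u.sequence)
                if b == "C" and offset + i not in planted
            ][:2]
            for pos in background:
                emit(u.seq_id, offset + pos, "m", cfg.mod_background_fraction)

        if cfg.include_filter_traps and self.uniques:
            u = self.uniques[0]
            offset = pad5[u.seq_id]
            c_positions = [i for i, b in enumerate(u.sequence) if b == "C"]
            non_c = [i for i, b in enumerate(u.sequence) if b != "C"]
            # minus-strand record: dropped by the strand filter
            emit(u.seq_id, offset + c_positions[-1], "m", 0.5, strand="-")
            # under the 100-valid-call floor: dropped by the depth filter
            emit(u.seq_id, offset + c_positions[-2], "m", 0.5, depth=50)
            # reference base does not match the unmodified base: dropped
            emit(u.seq_id, offset + non_c[0], "m", 0.5)

        write_bedmethyl(records, out_path)
        return pd.DataFrame(truth_rows)

    # -- whole-dataset emission -------------------------------------------

    def write_all(self, out_dir: str | Path) -> dict[str, object]:
        """Emit the complete dataset (reference, per-sample SAM + bedMethyl,
        sample sheet, truth tables) under ``out_dir``; returns a manifest of
        paths plus the in-memory truth."""
        cfg = self.config
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        gene_fasta = out / "genes.fasta"
        write_fasta(((g.gene_id, g.sequence) for g in self.genes), gene_fasta)
        annot = out / "genes.tsv"
        with open(annot, "w") as fh:
            fh.write("gene_id\tisotype\tanticodon\tsprinzl\n")
            for g in self.genes:
                fh.write(
                    f"{g.gene_id}\t{g.isotype}\t{g.anticodon}\t"
                    f"{','.join(g.sprinzl_labels or ())}\n"
                )

        samples = []
        read_truths = []
        mod_truths = []
        reads_ss = self._ss_reads.spawn(2 * cfg.n_replicates)
        mods_ss = self._ss_mods.spawn(2 * cfg.n_replicates)
        k = 0
        for cond, with_spikes in (("ctrl", False), ("exp", True)):
            for rep in range(cfg.n_replicates):
                sample_id = f"{cond}{rep + 1}"
                sam = out / f"{sample_id}.sam"
                bed = out / f"{sample_id}.bedmethyl"
                read_truths.append(
                    self.simulate_alignments(
                        sam,
                        sample_id,
                        with_spikes=with_spikes,
                        rng=np.random.default_rng(reads_ss[k]),
                    )
                )
                mod_truths.append(
                    self.simulate_modkit_pileup(
                        bed,
                        sample_id,
                        rng=np.random.default_rng(mods_ss[k]),
                    )
                )
                samples.append(
                    {
                        "sample_id": sample_id,
                        "condition": cond,
                        "replicate": rep + 1,
                        "treated": cond == "exp",
                        "sam": str(sam),
                        "bedmethyl": str(bed),
                    }
                )
                k += 1

        sheet = pd.DataFrame(samples)
        sheet[["sample_id", "condition", "replicate", "treated"]].to_csv(
            out / "samples.tsv", sep="\t", index=False
        )
        assert self.truth is not None
        self.truth.read_truth = pd.concat(read_truths, ignore_index=True)
        self.truth.mod_truth = pd.concat(mod_truths, ignore_index=True)
        self.truth.read_truth.to_csv(
            out / "truth_reads.tsv", sep="\t", index=False
        )
        self.truth.mod_truth.to_csv(
            out / "truth_modsites.tsv", sep="\t", index=False
        )
        if self.truth.error_rates is not None:
            self.truth.error_rates.to_csv(
                out / "truth_error_rates.tsv", sep="\t", index=False
            )
        return {
            "gene_fasta": str(gene_fasta),
            "annotation": str(annot),
            "samples": samples,
            "truth": self.truth,
        }
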