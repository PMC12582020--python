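"""Curated tRNA alignment reference.

Human tRNA gene sets are highly redundant: many loci encode the exact same
mature sequence, and distinct isodecoders can differ by a single nucleotide.
Aligning nanopore reads against every gene copy inflates multi-mapping, so
the reference is built from the *unique* mature sequences, each padded with
the library adapters so the aligner can anchor read ends. Sprinzl position
labels (the canonical tRNA coordinate system: 34 = wobble, 37, 58, "e"-arm
labels, insertion labels like "20a") are taken from the annotation table and
attached per sequence so that positions can be compared across tRNAs.

Sequences are held in the DNA alphabet internally (U is normalized to T on
read); all coordinates are 0-based half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

NOT_IN_BODY = "not-in-body"
"""Sentinel returned for positions outside the tRNA body (adapter pads)."""

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class TRNAGeneRecord:
    """One tRNA gene: mature sequence plus isotype/anticodon annotation."""

    gene_id: str
    sequence: str
    isotype: str
    anticodon: str
    sprinzl_labels: tuple[str, ...] | None = None
    source_locus: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.gene_id}: invalid characters in sequence: {sorted(bad)}"
            )
        if len(self.anticodon) != 3 or set(self.anticodon) - _VALID_BASES:
            raise ValueError(
                f"{self.gene_id}: malformed anticodon {self.anticodon!r}"
            )
        if self.sprinzl_labels is not None:
            if len(self.sprinzl_labels) != len(self.sequence):
                raise ValueError(
                    f"{self.gene_id}: {len(self.sprinzl_labels)} Sprinzl labels "
                    f"for a {len(self.sequence)} nt sequence"
                )
            # When the anticodon site is labelled, the sequence there must
            # match the annotated anticodon.
            label_pos = {lab: i for i, lab in enumerate(self.sprinzl_labels)}
            if all(str(p) in label_pos for p in (34, 35, 36)):
                site = "".join(
                    self.sequence[label_pos[str(p)]] for p in (34, 35, 36)
                )
                if site != self.anticodon:
                    raise ValueError(
                        f"{self.gene_id}: anticodon {self.anticodon} does not "
                        f"match sequence {site} at Sprinzl 34-36"
                    )

    @property
    def anticodon_label(self) -> str:
        """Isoacceptor label in the conventional 'Isotype-ANTICODON' form."""
        return f"{self.isotype}-{self.anticodon}"


@dataclass(frozen=True)
class UniqueTRNA:
    """A deduplicated tRNA sequence with the gene copies that share it."""

    seq_id: str
    sequence: str
    anticodon: str
    isotype: str
    member_gene_ids: tuple[str, ...]

    @property
    def anticodon_label(self) -> str:
        return f"{self.isotype}-{self.anticodon}"


@dataclass(frozen=True)
class PaddedReference:
    """A unique tRNA sequence flanked by the library adapter sequences."""

    seq_id: str
    padded_sequence: str
    pad5_len: int
    pad3_len: int

    @property
    def body_offset(self) -> int:
        """0-based start of the tRNA body within the padded sequence."""
        return self.pad5_len

    @property
    def body_length(self) -> int:
        return len(self.padded_sequence) - self.pad5_len - self.pad3_len

    @property
    def body(self) -> str:
        return self.padded_sequence[
            self.pad5_len : len(self.padded_sequence) - self.pad3_len
        ]


class SprinzlAnnotation:
    """Bidirectional map between linear body positions and Sprinzl labels."""

    def __init__(self, seq_id: str, labels: Sequence[str]) -> None:
        self.seq_id = seq_id
        self._pos2label: dict[int, str] = dict(enumerate(labels))
        self._label2pos: dict[str, int] = {}
        for pos, lab in self._pos2label.items():
            if lab in self._label2pos:
                raise ValueError(
                    f"{seq_id}: duplicate Sprinzl label {lab!r} "
                    f"(positions {self._label2pos[lab]} and {pos})"
                )
            self._label2pos[lab] = pos

    def __len__(self) -> int:
        return len(self._pos2label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._pos2label[i] for i in range(len(self._pos2label)))

    def sprinzl_of(self, linear_pos: int) -> str:
        """Label at a 0-based body position; pads return ``NOT_IN_BODY``."""
        return self._pos2label.get(linear_pos, NOT_IN_BODY)

    def linear_of(self, label: str) -> int | None:
        """0-based body position of a label, or None if this tRNA lacks it."""
        return self._label2pos.get(label)


def _normalize_seq(raw: str) -> str:
    return raw.strip().upper().replace("U", "T")


def _read_annotation_table(path: str | Path) -> dict[str, dict[str, str]]:
    table: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "isotype", "anticodon"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: annotation table must have columns {sorted(required)}"
            )
        for row in reader:
            table[row["gene_id"]] = row
    return table


def parse_gene_set(
    fasta_path: str | Path, annotation_table_path: str | Path
) -> list[TRNAGeneRecord]:
    """Parse a tRNA gene FASTA and join it with its annotation table.

    The table is tab-delimited with columns ``gene_id``, ``isotype``,
    ``anticodon`` and optionally ``sprinzl`` (comma-separated per-base
    labels). Every FASTA id must be present in the table.
    """
    table = _read_annotation_table(annotation_table_path)
    records: list[TRNAGeneRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = table.get(rec.id)
        if row is None:
            raise KeyError(
                f"FASTA id {rec.id!r} has no row in {annotation_table_path}"
            )
        labels_raw = (row.get("sprinzl") or "").strip()
        labels = (
            tuple(lab.strip() for lab in labels_raw.split(","))
            if labels_raw
            else None
        )
        records.append(
            TRNAGeneRecord(
                gene_id=rec.id,
                sequence=_normalize_seq(str(rec.seq)),
                isotype=row["isotype"].strip(),
                anticodon=_normalize_seq(row["anticodon"]),
                sprinzl_labels=labels,
                source_locus=(row.get("source_locus") or None),
            )
        )
    return records


def deduplicate(genes: Iterable[TRNAGeneRecord]) -> list[UniqueTRNA]:
    """Collapse gene records with identical sequences into unique tRNAs.

    The representative ``seq_id`` is the lexicographically smallest member
    gene id, making the reference reproducible across runs. Genes sharing a
    sequence must agree on anticodon and isotype.
    """
    by_seq: dict[str, list[TRNAGeneRecord]] = {}
    for g in genes:
        by_seq.setdefault(g.sequence, []).append(g)
    uniques: list[UniqueTRNA] = []
    for seq, members in by_seq.items():
        anticodons = {m.anticodon for m in members}
        isotypes = {m.isotype for m in members}
        if len(anticodons) > 1 or len(isotypes) > 1:
            ids = sorted(m.gene_id for m in members)
            raise ValueError(
                f"identical sequence with conflicting annotation among {ids}: "
                f"anticodons {sorted(anticodons)}, isotypes {sorted(isotypes)}"
            )
        member_ids = tuple(sorted(m.gene_id for m in members))
        uniques.append(
            UniqueTRNA(
                seq_id=member_ids[0],
                sequence=seq,
                anticodon=members[0].anticodon,
                isotype=members[0].isotype,
                member_gene_ids=member_ids,
            )
        )
    uniques.sort(key=lambda u: u.seq_id)
    return uniques


def count_anticodons(uniques: Iterable[UniqueTRNA]) -> int:
    """Number of distinct isoacceptors (isotype-anticodon pairs)."""
    return len({(u.isotype, u.anticodon) for u in uniques})


def build_padded_reference(
    uniques: Iterable[UniqueTRNA], adapter5: str = "", adapter3: str = ""
) -> list[PaddedReference]:
    """Flank every unique sequence with the library adapters.

    Padding with the adapter context lets the aligner anchor read ends that
    run into the adapters; empty adapters yield the bare bodies.
    """
    a5 = _normalize_seq(adapter5) if adapter5 else ""
    a3 = _normalize_seq(adapter3) if adapter3 else ""
    return [
        PaddedReference(
            seq_id=u.seq_id,
            padded_sequence=a5 + u.sequence + a3,
            pad5_len=len(a5),
            pad3_len=len(a3),
        )
        for u in uniques
    ]


def load_sprinzl(
    genes: Iterable[TRNAGeneRecord], uniques: Iterable[UniqueTRNA]
) -> dict[str, SprinzlAnnotation]:
    """Attach per-base Sprinzl labels to each unique sequence.

    Labels come from the member gene records (the curation is input data);
    members carrying labels must agree. Uniques whose members all lack
    labels are omitted from the result.
    """
    by_gene = {g.gene_id: g for g in genes}
    out: dict[str, SprinzlAnnotation] = {}
    for u in uniques:
        labelled = [
            by_gene[m].sprinzl_labels
            for m in u.member_gene_ids
            if m in by_gene and by_gene[m].sprinzl_labels is not None
        ]
        if not labelled:
            continue
        first = labelled[0]
        for other in labelled[1:]:
            if other != first:
                raise ValueError(
                    f"{u.seq_id}: member genes disagree on Sprinzl labels"
                )
        out[u.seq_id] = SprinzlAnnotation(u.seq_id, first)  # type: ignore[arg-type]
    return out


# ---------------------------------------------------------------------------
# I/O


def write_fasta(
    entries: Iterable[tuple[str, str]], path: str | Path
) -> None:
    """Write (id, sequence) pairs as single-line FASTA (byte-stable)."""
    with open(path, "w") as fh:
        for seq_id, seq in entries:
            fh.write(f">{seq_id}\n{seq}\n")


def write_reference_fasta(
    padded: Iterable[PaddedReference], path: str | Path
) -> None:
    write_fasta(((p.seq_id, p.padded_sequence) for p in padded), path)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: _normalize_seq(str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_uniques_table(
    uniques: Iterable[UniqueTRNA], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["seq_id", "anticodon", "isotype", "n_members", "member_gene_ids"]
        )
        for u in uniques:
            w.writerow(
                [
                    u.seq_id,
                    u.anticodon,
                    u.isotype,
                    len(u.member_gene_ids),
                    ",".join(u.member_gene_ids),
                ]
            )


def read_uniques_table(path: str | Path) -> dict[str, dict[str, str]]:
    """seq_id → row mapping; used downstream for anticodon lookups."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return {row["seq_id"]: row for row in reader}


def anticodon_lookup_from_table(
    path: str | Path,
) -> dict[str, str]:
    """seq_id → 'Isotype-ANTICODON' lookup from a uniques table on disk."""
    return {
        seq_id: f"{row['isotype']}-{row['anticodon']}"
        for seq_id, row in read_uniques_table(path).items()
    }


def write_sprinzl_table(
    annotations: Mapping[str, SprinzlAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["seq_id", "sprinzl"])
        for seq_id in sorted(annotations):
            w.writerow([seq_id, ",".join(annotations[seq_id].labels)])


def read_sprinzl_table(path: str | Path) -> dict[str, SprinzlAnnotation]:
    out: dict[str, SprinzlAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["seq_id"]] = SprinzlAnnotation(
                row["seq_id"], row["sprinzl"].split(",")
            )
    return out
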