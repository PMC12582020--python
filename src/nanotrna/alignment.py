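"""Mapping-quality recalibration (MOD-MAPQ) and anticodon assignment.

tRNA reference sequences are short and can differ by a single nucleotide,
so a short-read aligner reports many reads with MAPQ 0 even when the
primary alignment scores strictly better than every alternative. The
recalibrated mapping quality is the alignment-score gap between the primary
and the best alternative hit (AS_primary − AS_best_alt): when that gap is
positive and exceeds the originally reported MAPQ, the MAPQ is replaced by
the gap. Reads left at MAPQ 0 are rescued when all of their co-optimal hits
point at one reference sequence ("same target") or one anticodon
("same codon"); reads whose primary alignment is on the reverse strand are
antisense (a proxy for mis-mapping).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

MAPQ_CAP = 60  # conventional MAPQ ceiling assumed by downstream tools


class Category(str, enum.Enum):
    """Read assignment categories; every read receives exactly one."""

    UNIQUE = "unique"
    SAME_TARGET = "same_target"
    SAME_CODON = "same_codon"
    AMBIGUOUS = "ambiguous"
    ANTISENSE = "antisense"
    UNMAPPED = "unmapped"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories whose reads identify a single anticodon.
COUNTED_CATEGORIES = frozenset(
    {Category.UNIQUE, Category.SAME_TARGET, Category.SAME_CODON}
)


@dataclass(frozen=True)
class AlignmentHit:
    target_id: str
    strand: str  # "+" or "-"
    score: int  # aligner AS units
    is_primary: bool = False


@dataclass
class ReadHits:
    """One read's primary alignment plus its scored alternatives."""

    read_id: str
    primary: AlignmentHit | None
    alternatives: list[AlignmentHit]
    original_mapq: int = 0
    mean_base_quality: float = float("nan")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    mod_mapq: int
    category: Category
    anticodon: str | None
    target_id: str | None
    original_mapq: int = 0
    mean_base_quality: float = float("nan")


def recalibrate_mapq(hits: ReadHits) -> int:
    """Recalibrated mapping quality from the alignment-score gap.

    d = AS_primary − max(AS of alternatives). If d > 0 the mapping quality
    becomes max(original, d); otherwise the original MAPQ is kept. With no
    alternatives the original MAPQ is returned. Capped at 60.
    """
    if hits.primary is None:
        return 0
    if not hits.alternatives:
        return min(hits.original_mapq, MAPQ_CAP)
    d = hits.primary.score - max(h.score for h in hits.alternatives)
    if d > 0:
        return min(max(hits.original_mapq, d), MAPQ_CAP)
    return min(hits.original_mapq, MAPQ_CAP)


def classify(
    hits: ReadHits, mod_mapq: int, anticodon_lookup: Mapping[str, str]
) -> ReadAssignment:
    """Assign a read to a category (and anticodon where identified).

    Rules, in order: unmapped; antisense (reverse-strand primary); unique
    (mod_mapq ≥ 1); then for mod_mapq 0 the equal-top-score hit set (strict
    AS equality with the primary) decides same_target / same_codon /
    ambiguous.
    """
    base = dict(
        read_id=hits.read_id,
        mod_mapq=mod_mapq,
        original_mapq=hits.original_mapq,
        mean_base_quality=hits.mean_base_quality,
    )
    if hits.primary is None:
        return ReadAssignment(
            category=Category.UNMAPPED, anticodon=None, target_id=None, **base
        )
    primary = hits.primary
    if primary.target_id not in anticodon_lookup:
        raise KeyError(f"unknown target id {primary.target_id!r}")
    if primary.strand == "-":
        return ReadAssignment(
            category=Category.ANTISENSE,
            anticodon=None,
            target_id=primary.target_id,
            **base,
        )
    anticodon = anticodon_lookup[primary.target_id]
    if mod_mapq >= 1:
        return ReadAssignment(
            category=Category.UNIQUE,
            anticodon=anticodon,
            target_id=primary.target_id,
            **base,
        )
    top = [primary] + [
        h for h in hits.alternatives if h.score == primary.score
    ]
    targets = {h.target_id for h in top}
    if targets == {primary.target_id}:
        return ReadAssignment(
            category=Category.SAME_TARGET,
            anticodon=anticodon,
            target_id=primary.target_id,
            **base,
        )
    for t in targets:
        if t not in anticodon_lookup:
            raise KeyError(f"unknown target id {t!r}")
    if {anticodon_lookup[t] for t in targets} == {anticodon}:
        return ReadAssignment(
            category=Category.SAME_CODON,
            anticodon=anticodon,
            target_id=None,
            **base,
        )
    return ReadAssignment(
        category=Category.AMBIGUOUS, anticodon=None, target_id=None, **base
    )


# ---------------------------------------------------------------------------
# SAM/BAM processing


def _mean_quality(qualities) -> float:
    if qualities is None or len(qualities) == 0:
        return float("nan")
    return float(sum(qualities)) / len(qualities)


def _hit_from_record(rec: pysam.AlignedSegment, is_primary: bool) -> AlignmentHit:
    return AlignmentHit(
        target_id=rec.reference_name,
        strand="-" if rec.is_reverse else "+",
        score=int(rec.get_tag("AS")),
        is_primary=is_primary,
    )


def group_read_hits(
    records: Iterable[pysam.AlignedSegment],
) -> tuple[dict[str, ReadHits], dict[str, int]]:
    """Group alignment records by read name into ReadHits.

    Supplementary records are excluded; secondary records lacking an AS tag
    are dropped and counted. Works on unsorted input (full collation pass).
    """
    hits: dict[str, ReadHits] = {}
    dropped = {"no_AS_secondary": 0, "supplementary": 0}
    for rec in records:
        if rec.is_supplementary:
            dropped["supplementary"] += 1
            continue
        rh = hits.setdefault(
            rec.query_name,
            ReadHits(read_id=rec.query_name, primary=None, alternatives=[]),
        )
        if rec.is_unmapped:
            continue
        if rec.is_secondary:
            if not rec.has_tag("AS"):
                dropped["no_AS_secondary"] += 1
                continue
            rh.alternatives.append(_hit_from_record(rec, is_primary=False))
        else:
            if not rec.has_tag("AS"):
                raise ValueError(
                    f"primary record for {rec.query_name!r} lacks an AS tag"
                )
            rh.primary = _hit_from_record(rec, is_primary=True)
            rh.original_mapq = rec.mapping_quality
            rh.mean_base_quality = _mean_quality(rec.query_qualities)
    return hits, dropped


def assignments_frame(assignments: Iterable[ReadAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "category": a.category.value,
                "anticodon": a.anticodon,
                "target_id": a.target_id,
                "mod_mapq": a.mod_mapq,
                "original_mapq": a.original_mapq,
                "mean_base_quality": a.mean_base_quality,
            }
            for a in assignments
        ],
        columns=[
            "read_id",
            "category",
            "anticodon",
            "target_id",
            "mod_mapq",
            "original_mapq",
            "mean_base_quality",
        ],
    )


def process_alignments(
    bam_in: str | Path,
    anticodon_lookup: Mapping[str, str],
    bam_out: str | Path | None = None,
    assignments_out: str | Path | None = None,
) -> pd.DataFrame:
    """Recalibrate MAPQ on a SAM/BAM and assign every read.

    The output file is the input with the MAPQ of primary records replaced
    by MOD-MAPQ; everything else (including MM/ML base-modification tags) is
    passed through untouched. Returns the per-read assignments table.
    """
    mode = "rb" if str(bam_in).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(bam_in), mode, check_sq=False) as fh:
        header = fh.header.to_dict()
        records = list(fh)

    hits, dropped = group_read_hits(records)
    if any(dropped.values()):
        logger.info("dropped records: %s", dropped)

    assignments: list[ReadAssignment] = []
    mod_mapqs: dict[str, int] = {}
    for read_id, rh in hits.items():
        mq = recalibrate_mapq(rh)
        mod_mapqs[read_id] = mq
        assignments.append(classify(rh, mq, anticodon_lookup))

    if bam_out is not None:
        wmode = "wb" if str(bam_out).endswith(".bam") else "w"
        with pysam.AlignmentFile(
            str(bam_out), wmode, header=pysam.AlignmentHeader.from_dict(header)
        ) as out:
            for rec in records:
                if (
                    not rec.is_unmapped
                    and not rec.is_secondary
                    and not rec.is_supplementary
                ):
                    rec.mapping_quality = mod_mapqs[rec.query_name]
                out.write(rec)

    frame = assignments_frame(assignments)
    counts = frame["category"].value_counts().to_dict()
    logger.info("assignment categories: %s", counts)
    if assignments_out is not None:
        frame.to_csv(assignments_out, sep="\t", index=False)
    return frame
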