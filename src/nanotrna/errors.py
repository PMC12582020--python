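"""Base-calling error profiles as evidence for tRNA modifications.

Many tRNA modifications perturb the nanopore current enough to produce
systematic base-calling errors (mismatches and deletions) at or around the
modified position. Per reference position this module counts sequencing
events (match / mismatch / deletion; insertions are tracked but excluded
from events) and derives:

* relative error = (mismatches + deletions) / total events,
* reference-base fraction = count of the reference base / total events,

which sum to 1 by construction. Condition contrasts are expressed as the
log2 ratio of mean relative errors (experiment over control), and a global
per-Sprinzl-position screen runs a two-sample t-test per position label over
the per-tRNA relative errors of the two conditions, Benjamini–Hochberg
corrected across labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats as _scipy_stats

from nanotrna.reference import NOT_IN_BODY, SprinzlAnnotation, read_fasta

DEFAULT_MIN_MAPQ = 1
DEFAULT_MIN_BASEQ = 2
DEFAULT_MAX_DEPTH = 50_000
DEFAULT_MIN_EVENTS = 80

_BASES = ("A", "C", "G", "T")


@dataclass
class PositionPileup:
    """Event counts at one reference position.

    ``total_events`` counts matches, mismatches and deletions; insertions
    are attributed to the position left of the inserted bases and excluded.
    """

    seq_id: str
    position: int  # 0-based reference coordinate
    ref_base: str
    counts: dict[str, int] = field(
        default_factory=lambda: {
            "A": 0, "C": 0, "G": 0, "T": 0, "deletion": 0, "insertion": 0
        }
    )

    @property
    def total_events(self) -> int:
        return sum(self.counts[k] for k in (*_BASES, "deletion"))


def relative_error(p: PositionPileup, include_deletions: bool = True) -> float | None:
    """Incorrect calls over total events; None when there are no events."""
    total = p.total_events
    if total == 0:
        return None
    mismatches = sum(p.counts[b] for b in _BASES if b != p.ref_base)
    bad = mismatches + (p.counts["deletion"] if include_deletions else 0)
    denom = total if include_deletions else total - p.counts["deletion"]
    if denom == 0:
        return None
    return bad / denom


def ref_base_fraction(p: PositionPileup) -> float | None:
    """Reference-base count over canonical bases plus deletions."""
    total = p.total_events
    if total == 0:
        return None
    return p.counts[p.ref_base] / total


def build_pileup(
    bam_path: str | Path,
    reference: str | Path | Mapping[str, str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> dict[str, dict[int, PositionPileup]]:
    """Count per-position events from an aligned (recalibrated) SAM/BAM.

    Reads below ``min_mapq`` are skipped; base calls below ``min_baseq`` are
    skipped (deletions carry no base quality and always count). The depth
    cap is applied per position, first-come in file order, so results are
    deterministic. Secondary/supplementary records are excluded.
    """
    if isinstance(reference, (str, Path)):
        ref_seqs = read_fasta(reference)
    else:
        ref_seqs = dict(reference)

    pileups: dict[str, dict[int, PositionPileup]] = {}
    mode = "rb" if str(bam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(bam_path), mode, check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.mapping_quality < min_mapq
            ):
                continue
            seq_id = rec.reference_name
            if seq_id not in ref_seqs:
                raise KeyError(
                    f"BAM contig {seq_id!r} absent from the reference FASTA"
                )
            ref_seq = ref_seqs[seq_id]
            per_seq = pileups.setdefault(seq_id, {})
            quals = rec.query_qualities
            qseq = rec.query_sequence
            last_ref: int | None = None
            for qpos, rpos in rec.get_aligned_pairs():
                if rpos is not None and qpos is not None:
                    last_ref = rpos
                    if quals is not None and quals[qpos] < min_baseq:
                        continue
                    base = qseq[qpos].upper()
                    if base not in _BASES:
                        continue
                    pp = per_seq.get(rpos)
                    if pp is None:
                        pp = per_seq[rpos] = PositionPileup(
                            seq_id, rpos, ref_seq[rpos]
                        )
                    if pp.total_events >= max_depth:
                        continue
                    pp.counts[base] += 1
                elif rpos is not None:  # deletion in the read
                    last_ref = rpos
                    pp = per_seq.get(rpos)
                    if pp is None:
                        pp = per_seq[rpos] = PositionPileup(
                            seq_id, rpos, ref_seq[rpos]
                        )
                    if pp.total_events >= max_depth:
                        continue
                    pp.counts["deletion"] += 1
                elif qpos is not None and last_ref is not None:
                    # insertion: attributed left, tracked but not an event
                    pp = per_seq.get(last_ref)
                    if pp is not None:
                        pp.counts["insertion"] += 1
    return pileups


def error_profile(
    pileups: Mapping[str, Mapping[int, PositionPileup]],
    min_events: int = DEFAULT_MIN_EVENTS,
    body_offsets: Mapping[str, int] | None = None,
    body_lengths: Mapping[str, int] | None = None,
    include_deletions: bool = True,
) -> pd.DataFrame:
    """Per-position error statistics table for one sample/replicate.

    Positions with fewer than ``min_events`` events are excluded. When
    ``body_offsets``/``body_lengths`` are given (padded reference),
    positions are reported in body coordinates and adapter-pad positions
    are dropped.
    """
    rows = []
    for seq_id, per_seq in pileups.items():
        offset = body_offsets.get(seq_id, 0) if body_offsets else 0
        blen = body_lengths.get(seq_id) if body_lengths else None
        for rpos in sorted(per_seq):
            pp = per_seq[rpos]
            if pp.total_events < min_events:
                continue
            body_pos = rpos - offset
            if body_pos < 0 or (blen is not None and body_pos >= blen):
                continue
            rows.append(
                {
                    "seq_id": seq_id,
                    "position": body_pos,
                    "ref_base": pp.ref_base,
                    "relative_error": relative_error(pp, include_deletions),
                    "ref_base_fraction": ref_base_fraction(pp),
                    "total_events": pp.total_events,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "position",
            "ref_base",
            "relative_error",
            "ref_base_fraction",
            "total_events",
        ],
    )


def _mean_over_replicates(profiles: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean relative error per (seq_id, position) across replicates.

    Only positions passing the event filter in *every* replicate are kept,
    to avoid replicate-composition artifacts.
    """
    keys = None
    for prof in profiles:
        k = set(zip(prof["seq_id"], prof["position"]))
        keys = k if keys is None else keys & k
    keys = keys or set()
    frames = []
    for i, prof in enumerate(profiles):
        sub = prof[
            [
                (s, p) in keys
                for s, p in zip(prof["seq_id"], prof["position"])
            ]
        ][["seq_id", "position", "relative_error"]].copy()
        sub["replicate"] = i
        frames.append(sub)
    if not frames or all(len(f) == 0 for f in frames):
        return pd.DataFrame(columns=["seq_id", "position", "mean_error"])
    allrep = pd.concat(frames, ignore_index=True)
    out = (
        allrep.groupby(["seq_id", "position"])["relative_error"]
        .mean()
        .reset_index(name="mean_error")
    )
    return out


def condition_log2_ratio(
    exp_profiles: Sequence[pd.DataFrame],
    ctrl_profiles: Sequence[pd.DataFrame],
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """log2 of mean experimental over mean control relative error.

    Positions must pass the event filter in every replicate of both
    conditions. A zero control mean yields +inf (or -inf for a zero
    experimental mean over nonzero control) unless a ``pseudocount`` is
    supplied for plotting.
    """
    exp = _mean_over_replicates(exp_profiles).rename(
        columns={"mean_error": "mean_exp"}
    )
    ctrl = _mean_over_replicates(ctrl_profiles).rename(
        columns={"mean_error": "mean_ctrl"}
    )
    merged = exp.merge(ctrl, on=["seq_id", "position"], how="inner")

    def ratio(row) -> float:
        e, c = row["mean_exp"], row["mean_ctrl"]
        if pseudocount is not None:
            e, c = e + pseudocount, c + pseudocount
        if c == 0:
            return math.inf if e > 0 else math.nan
        if e == 0:
            return -math.inf
        return math.log2(e / c)

    merged["log2_ratio"] = merged.apply(ratio, axis=1) if len(merged) else []
    return merged


# ---------------------------------------------------------------------------
# Statistics: Welch t and Benjamini–Hochberg (closed forms, cross-checked in
# tests against scipy/statsmodels)


def welch_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test: returns (t, two-sided p, degrees of freedom).

    Welch (unequal variances) by default; ``equal_var=True`` pools. With
    zero variance in both groups the statistic degenerates: equal means give
    (0, 1), unequal means (±inf, 0).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least two observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if equal_var:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        denom = math.sqrt(sp2 * (1 / nx + 1 / ny))
    else:
        se2 = vx / nx + vy / ny
        denom = math.sqrt(se2)
        if se2 > 0:
            # Welch–Satterthwaite, normalized by se2 to avoid underflow
            fx = (vx / nx) / se2
            fy = (vy / ny) / se2
            df = 1.0 / (fx**2 / (nx - 1) + fy**2 / (ny - 1))
        else:
            df = nx + ny - 2
    diff = mx - my
    if denom == 0:
        if diff == 0:
            return 0.0, 1.0, float(df)
        return math.copysign(math.inf, diff), 0.0, float(df)
    t = diff / denom
    p = 2.0 * float(_scipy_stats.t.sf(abs(t), df))
    return float(t), p, float(df)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up, monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted


def global_position_test(
    profiles_by_condition: Mapping[str, Sequence[pd.DataFrame]],
    sprinzl: Mapping[str, SprinzlAnnotation],
    equal_var: bool = False,
    min_group: int = 2,
) -> pd.DataFrame:
    """Per-Sprinzl-label t-tests between two conditions, BH corrected.

    For each condition, replicate profiles are averaged per (tRNA,
    position); positions are then grouped by Sprinzl label, so each tRNA
    contributes one observation per label per condition. Labels with fewer
    than ``min_group`` observations in either group are skipped.
    """
    if len(profiles_by_condition) != 2:
        raise ValueError("exactly two conditions are required")
    (name_a, prof_a), (name_b, prof_b) = profiles_by_condition.items()

    def by_label(profiles: Sequence[pd.DataFrame]) -> dict[str, list[float]]:
        mean = _mean_over_replicates(profiles)
        groups: dict[str, list[float]] = {}
        for seq_id, pos, err in zip(
            mean["seq_id"], mean["position"], mean["mean_error"]
        ):
            ann = sprinzl.get(seq_id)
            if ann is None:
                continue
            label = ann.sprinzl_of(int(pos))
            if label == NOT_IN_BODY:
                continue
            groups.setdefault(label, []).append(float(err))
        return groups

    ga, gb = by_label(prof_a), by_label(prof_b)
    rows = []
    for label in sorted(set(ga) & set(gb)):
        xa, xb = ga[label], gb[label]
        if len(xa) < min_group or len(xb) < min_group:
            continue
        t, p, df = welch_t(xa, xb, equal_var=equal_var)
        rows.append(
            {
                "sprinzl": label,
                f"n_{name_a}": len(xa),
                f"n_{name_b}": len(xb),
                "t": t,
                "df": df,
                "pvalue": p,
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["padj"] = bh_adjust(result["pvalue"].to_numpy())
    else:
        result["padj"] = []
    return result


def site_error_report(
    profiles_by_condition: Mapping[str, Sequence[pd.DataFrame]],
    seq_id: str,
    labels: Sequence[str],
    sprinzl: Mapping[str, SprinzlAnnotation],
) -> pd.DataFrame:
    """Replicate mean ± sd of relative error at chosen Sprinzl labels.

    Mirrors a per-tRNA site report (e.g. positions 36–38 of Phe-GAA across
    conditions). Labels the tRNA lacks yield rows with absent values; a
    single replicate reports sd as absent.
    """
    ann = sprinzl.get(seq_id)
    rows = []
    for cond, profiles in profiles_by_condition.items():
        for label in labels:
            pos = ann.linear_of(label) if ann is not None else None
            values: list[float] = []
            if pos is not None:
                for prof in profiles:
                    hit = prof[
                        (prof["seq_id"] == seq_id) & (prof["position"] == pos)
                    ]
                    if len(hit):
                        values.append(float(hit["relative_error"].iloc[0]))
            rows.append(
                {
                    "condition": cond,
                    "seq_id": seq_id,
                    "sprinzl": label,
                    "n_replicates": len(values),
                    "mean_error": float(np.mean(values)) if values else math.nan,
                    "sd_error": (
                        float(np.std(values, ddof=1))
                        if len(values) > 1
                        else math.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
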