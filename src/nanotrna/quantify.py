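"""Per-anticodon expression quantification and mapping QC.

Reads are counted per anticodon (isoacceptor), per recalibrated MAPQ value
and per assignment category; the expression matrix then sums the MAPQ > 0
counts with the MAPQ-0 "same codon" (and, by default, "same target")
rescues. Columns are normalized to a fixed sum of 1000 so isoacceptor
proportions are comparable across samples of different depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from nanotrna.alignment import Category

DEFAULT_MIN_READ_QUAL = 4.0
DEFAULT_FIXED_SUM = 1000.0


@dataclass(frozen=True)
class MappingQC:
    """Mapped/antisense breakdown for one sample (antisense ~ mis-mapping)."""

    sample_id: str
    n_mapped: int
    n_unmapped: int
    fraction_proper: float  # of mapped reads; NaN when nothing mapped
    fraction_antisense: float


def count_per_mapq_bin(
    assignments: pd.DataFrame,
    min_read_qual: float = DEFAULT_MIN_READ_QUAL,
) -> pd.DataFrame:
    """QC counts per (anticodon, mod_mapq, category).

    Only forward-strand mapped reads with mean base-call quality strictly
    above ``min_read_qual`` are counted. MAPQ-0 rescues appear in the 0 bin
    under their category; ambiguous reads are binned under their primary
    hit's anticodon (they are never summed into expression).
    """
    df = assignments[
        ~assignments["category"].isin(
            [Category.ANTISENSE.value, Category.UNMAPPED.value]
        )
    ]
    df = df[df["mean_base_quality"] > min_read_qual]
    binned = (
        df.groupby(["anticodon", "mod_mapq", "category"], dropna=False)
        .size()
        .reset_index(name="count")
    )
    return binned


def expression_matrix(
    bins_by_sample: Mapping[str, pd.DataFrame],
    include_same_target: bool = True,
) -> pd.DataFrame:
    """Anticodon × sample raw count matrix from per-bin QC tables.

    Sums the MAPQ > 0 counts plus the MAPQ-0 "same codon" rescue; "same
    target" reads also identify a single anticodon and are included unless
    ``include_same_target`` is False (the strict reading).
    """
    counted = {Category.UNIQUE.value, Category.SAME_CODON.value}
    if include_same_target:
        counted.add(Category.SAME_TARGET.value)
    columns: dict[str, pd.Series] = {}
    for sample, bins in bins_by_sample.items():
        keep = bins[
            bins["category"].isin(counted)
            & (
                (bins["mod_mapq"] > 0)
                | bins["category"].isin(
                    {Category.SAME_CODON.value, Category.SAME_TARGET.value}
                )
            )
        ]
        columns[sample] = keep.groupby("anticodon")["count"].sum()
    matrix = pd.DataFrame(columns).fillna(0).astype(int)
    matrix = matrix.sort_index()
    matrix.index.name = "anticodon"
    return matrix


def normalize_fixed_sum(
    matrix: pd.DataFrame, total: float = DEFAULT_FIXED_SUM
) -> pd.DataFrame:
    """Scale every sample column to sum to ``total`` (default 1000)."""
    sums = matrix.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(
            f"cannot normalize all-zero sample column(s): {list(zero.index)}"
        )
    return matrix.astype(float) * (total / sums)


def mapping_qc(assignments: pd.DataFrame, sample_id: str = "") -> MappingQC:
    """Proper (forward) vs antisense fractions over mapped reads."""
    n_unmapped = int((assignments["category"] == Category.UNMAPPED.value).sum())
    mapped = assignments[assignments["category"] != Category.UNMAPPED.value]
    n_mapped = len(mapped)
    if n_mapped == 0:
        return MappingQC(sample_id, 0, n_unmapped, float("nan"), float("nan"))
    n_anti = int((mapped["category"] == Category.ANTISENSE.value).sum())
    return MappingQC(
        sample_id=sample_id,
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
        fraction_proper=(n_mapped - n_anti) / n_mapped,
        fraction_antisense=n_anti / n_mapped,
    )


def mapping_qc_frame(qcs: list[MappingQC]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "n_mapped": q.n_mapped,
                "n_unmapped": q.n_unmapped,
                "fraction_proper": q.fraction_proper,
                "fraction_antisense": q.fraction_antisense,
            }
            for q in qcs
        ]
    )


def replicate_correlation(matrix: pd.DataFrame, a: str, b: str) -> float:
    """Pearson correlation between two sample columns (e.g. replicates)."""
    x = matrix[a].to_numpy(dtype=float)
    y = matrix[b].to_numpy(dtype=float)
    if len(x) < 2:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
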