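"""bedMethyl modification-pileup filtering and cross-method comparison.

The RNA004 base-caller emits per-read modification probabilities for a few
common modifications (m5C, m6A, pseudouridine); modkit's pileup summarises
them per reference position as the "fraction modified": confident modified
calls over all confident calls. This module parses that bedMethyl dialect,
applies the standard filters (plus strand, reference base matching the
unmodified base, a minimum of 100 valid calls), averages per-site fractions
over the untreated samples, thresholds at >0/>10/>20%, and compares the
resulting site sets with orthogonal chemical-method site tables (e.g.
bisulfite-based m5C or Ψ-cyclization sequencing) keyed on
(tRNA, Sprinzl label).

Known caveat carried over from the underlying caller: isomeric
modifications are not separable (m1A at 58 reported as m6A, m3C at 32 as
m5C); sites at those positions should be read accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from nanotrna.reference import NOT_IN_BODY, SprinzlAnnotation

DEFAULT_MIN_VALID = 100
DEFAULT_CUTOFFS = (0.0, 10.0, 20.0)  # percent

#: bedMethyl modification codes → canonical (unmodified) base, DNA alphabet.
MOD_CODE_CANONICAL = {"m": "C", "a": "A", "17802": "T"}
MOD_CODE_NAME = {"m": "m5C", "a": "m6A", "17802": "pseU"}


@dataclass(frozen=True)
class ModPileupRecord:
    """One bedMethyl line: confident-call counts at one position."""

    seq_id: str
    position: int  # 0-based
    strand: str
    mod_code: str
    n_valid: int
    n_mod: int
    n_canonical: int = 0
    n_other_mod: int = 0
    n_delete: int = 0
    n_fail: int = 0
    n_diff: int = 0
    n_nocall: int = 0

    def __post_init__(self) -> None:
        if self.n_mod > self.n_valid:
            raise ValueError(
                f"{self.seq_id}:{self.position} {self.mod_code}: "
                f"n_mod {self.n_mod} exceeds n_valid {self.n_valid}"
            )

    @property
    def fraction_modified(self) -> float:
        return self.n_mod / self.n_valid if self.n_valid else 0.0

    @property
    def canonical_base(self) -> str:
        return MOD_CODE_CANONICAL[self.mod_code]


@dataclass(frozen=True)
class ModSite:
    """Per-site modification probability averaged over samples."""

    seq_id: str
    position: int
    mod_code: str
    mean_fraction: float
    n_samples: int
    sprinzl: str | None = None
    anticodon: str | None = None

    @property
    def mean_percent(self) -> float:
        return 100.0 * self.mean_fraction


@dataclass
class SiteSetComparison:
    """Overlap of two site sets keyed on (tRNA identifier, Sprinzl label)."""

    shared: list[tuple[str, str]]
    left_only: list[tuple[str, str]]
    right_only: list[tuple[str, str]]
    unmapped_right: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_left_only(self) -> int:
        return len(self.left_only)

    @property
    def n_right_only(self) -> int:
        return len(self.right_only)


def parse_bedmethyl(path: str | Path) -> list[ModPileupRecord]:
    """Parse a modkit-dialect bedMethyl file.

    Columns 1–9 are BED9 (name = mod code, score = n_valid); columns 10–18
    are Nvalid, percent modified, Nmod, Ncanonical, Nother_mod, Ndelete,
    Nfail, Ndiff, Nnocall. modkit separates the trailing block with spaces,
    so the parser splits on any whitespace. Unknown modification codes are
    skipped with a warning; a malformed line is a hard error naming it.
    """
    records: list[ModPileupRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 18:
                raise ValueError(
                    f"{path}:{lineno}: expected 18 bedMethyl fields, "
                    f"got {len(fields)}"
                )
            mod_code = fields[3]
            if mod_code not in MOD_CODE_CANONICAL:
                warnings.warn(
                    f"{path}:{lineno}: unknown modification code "
                    f"{mod_code!r}, skipping",
                    stacklevel=2,
                )
                continue
            try:
                rec = ModPileupRecord(
                    seq_id=fields[0],
                    position=int(fields[1]),
                    strand=fields[5],
                    mod_code=mod_code,
                    n_valid=int(fields[9]),
                    n_mod=int(fields[11]),
                    n_canonical=int(fields[12]),
                    n_other_mod=int(fields[13]),
                    n_delete=int(fields[14]),
                    n_fail=int(fields[15]),
                    n_diff=int(fields[16]),
                    n_nocall=int(fields[17]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            # sanity: the printed percent must agree with the counts
            # (tolerate the two-decimal rounding modkit applies)
            percent = float(fields[10])
            if rec.n_valid and abs(percent - 100.0 * rec.fraction_modified) > 0.01:
                raise ValueError(
                    f"{path}:{lineno}: percent column {percent} inconsistent "
                    f"with counts {rec.n_mod}/{rec.n_valid}"
                )
            records.append(rec)
    return records


def write_bedmethyl(
    records: Iterable[ModPileupRecord], path: str | Path
) -> None:
    """Write records in the modkit dialect (tab BED9, space-separated rest)."""
    with open(path, "w") as fh:
        for r in records:
            bed9 = "\t".join(
                [
                    r.seq_id,
                    str(r.position),
                    str(r.position + 1),
                    r.mod_code,
                    str(r.n_valid),
                    r.strand,
                    str(r.position),
                    str(r.position + 1),
                    "255,0,0",
                ]
            )
            rest = " ".join(
                [
                    str(r.n_valid),
                    f"{100.0 * r.fraction_modified:.2f}",
                    str(r.n_mod),
                    str(r.n_canonical),
                    str(r.n_other_mod),
                    str(r.n_delete),
                    str(r.n_fail),
                    str(r.n_diff),
                    str(r.n_nocall),
                ]
            )
            fh.write(f"{bed9}\t{rest}\n")


def filter_records(
    records: Iterable[ModPileupRecord],
    reference: Mapping[str, str],
    min_valid: int = DEFAULT_MIN_VALID,
) -> list[ModPileupRecord]:
    """Keep plus-strand records whose reference base is the unmodified base
    of the called modification and which have at least ``min_valid``
    confident calls. Order-independent and idempotent."""
    kept = []
    for r in records:
        if r.strand != "+":
            continue
        seq = reference.get(r.seq_id)
        if seq is None or r.position >= len(seq):
            continue
        if seq[r.position].upper() != r.canonical_base:
            continue
        if r.n_valid < min_valid:
            continue
        kept.append(r)
    return kept


def average_sites(
    records_by_sample: Mapping[str, Sequence[ModPileupRecord]],
    include_samples: Sequence[str] | None = None,
) -> list[ModSite]:
    """Unweighted mean modified fraction per (tRNA, position, mod) over
    samples. Samples where a site is absent contribute no term. The
    included set should be the untreated samples, given explicitly (e.g.
    from a sample sheet), never inferred from file names."""
    samples = (
        list(records_by_sample)
        if include_samples is None
        else list(include_samples)
    )
    acc: dict[tuple[str, int, str], list[float]] = {}
    for sample in samples:
        for r in records_by_sample.get(sample, []):
            acc.setdefault((r.seq_id, r.position, r.mod_code), []).append(
                r.fraction_modified
            )
    return [
        ModSite(
            seq_id=seq_id,
            position=pos,
            mod_code=code,
            mean_fraction=sum(vals) / len(vals),
            n_samples=len(vals),
        )
        for (seq_id, pos, code), vals in sorted(acc.items())
    ]


def annotate_sites(
    sites: Iterable[ModSite],
    sprinzl: Mapping[str, SprinzlAnnotation],
    body_offsets: Mapping[str, int] | None = None,
    anticodon_lookup: Mapping[str, str] | None = None,
) -> list[ModSite]:
    """Attach Sprinzl labels (and isoacceptor labels) to averaged sites.

    Positions on the adapter pads or on tRNAs without annotation keep
    ``sprinzl=None`` and are excluded from Sprinzl-keyed comparisons.
    """
    out = []
    for s in sites:
        offset = body_offsets.get(s.seq_id, 0) if body_offsets else 0
        ann = sprinzl.get(s.seq_id)
        label = ann.sprinzl_of(s.position - offset) if ann else None
        if label == NOT_IN_BODY:
            label = None
        out.append(
            ModSite(
                seq_id=s.seq_id,
                position=s.position,
                mod_code=s.mod_code,
                mean_fraction=s.mean_fraction,
                n_samples=s.n_samples,
                sprinzl=label,
                anticodon=(
                    anticodon_lookup.get(s.seq_id)
                    if anticodon_lookup
                    else None
                ),
            )
        )
    return out


def threshold_sites(
    sites: Iterable[ModSite], cutoff_percent: float
) -> list[ModSite]:
    """Keep sites with mean probability strictly above the percent cutoff."""
    return [s for s in sites if s.mean_percent > cutoff_percent]


def rollup_anticodon(sites: Iterable[ModSite]) -> list[ModSite]:
    """Roll isodecoder-level sites up to anticodon level.

    Per (isoacceptor, Sprinzl label, mod code) the maximum mean probability
    across isodecoders is kept (a site modified in any isodecoder of the
    family counts as modified for the family).
    """
    best: dict[tuple[str, str, str], ModSite] = {}
    for s in sites:
        if s.anticodon is None or s.sprinzl is None:
            continue
        key = (s.anticodon, s.sprinzl, s.mod_code)
        if key not in best or s.mean_fraction > best[key].mean_fraction:
            best[key] = s
    return [
        ModSite(
            seq_id=site.anticodon or site.seq_id,
            position=site.position,
            mod_code=site.mod_code,
            mean_fraction=site.mean_fraction,
            n_samples=site.n_samples,
            sprinzl=site.sprinzl,
            anticodon=site.anticodon,
        )
        for site in best.values()
    ]


def compare_orthogonal(
    nanopore_sites: Iterable[ModSite],
    orthogonal: pd.DataFrame,
    min_orthogonal_rate: float = 0.0,
    key: str = "anticodon",
    known_trnas: set[str] | None = None,
) -> SiteSetComparison:
    """Overlap nanopore sites with an orthogonal-method site table.

    ``orthogonal`` needs columns ``trna``, ``sprinzl`` and ``rate``
    (percent); rows at or below ``min_orthogonal_rate`` are dropped first
    (0 keeps all reported sites; 10 reproduces a high-confidence Ψ
    pre-filter). Site keys are (tRNA identifier, Sprinzl label) with the
    tRNA identifier at ``key`` level: "anticodon" (isoacceptor roll-up) or
    "isodecoder" (seq_id). Orthogonal rows naming a tRNA absent from
    ``known_trnas`` (when given) are reported as unmapped, not silently
    dropped.
    """
    required = {"trna", "sprinzl", "rate"}
    if not required <= set(orthogonal.columns):
        raise ValueError(f"orthogonal table must have columns {sorted(required)}")

    left = set()
    for s in nanopore_sites:
        if s.sprinzl is None:
            continue
        ident = s.anticodon if key == "anticodon" else s.seq_id
        if ident is None:
            continue
        left.add((ident, s.sprinzl))

    right = set()
    unmapped = []
    filtered = orthogonal[orthogonal["rate"] > min_orthogonal_rate]
    for trna, label in zip(filtered["trna"], filtered["sprinzl"]):
        k = (str(trna), str(label))
        if known_trnas is not None and k[0] not in known_trnas:
            unmapped.append(k)
            continue
        right.add(k)

    return SiteSetComparison(
        shared=sorted(left & right),
        left_only=sorted(left - right),
        right_only=sorted(right - left),
        unmapped_right=sorted(unmapped),
    )


def sites_frame(sites: Iterable[ModSite]) -> pd.DataFrame:
    """Tabular view of sites (probabilities rendered as percent)."""
    return pd.DataFrame(
        [
            {
                "seq_id": s.seq_id,
                "anticodon": s.anticodon,
                "position": s.position,
                "sprinzl": s.sprinzl,
                "mod": MOD_CODE_NAME.get(s.mod_code, s.mod_code),
                "mod_code": s.mod_code,
                "mean_percent": s.mean_percent,
                "n_samples": s.n_samples,
            }
            for s in sites
        ]
    )


def heatmap_matrix(sites: Iterable[ModSite]) -> pd.DataFrame:
    """Anticodon × Sprinzl-label matrix of mean percent (heatmap input)."""
    df = sites_frame(sites)
    df = df[df["sprinzl"].notna() & df["anticodon"].notna()]
    if df.empty:
        return pd.DataFrame()
    return df.pivot_table(
        index="anticodon",
        columns="sprinzl",
        values="mean_percent",
        aggfunc="max",
    )
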