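"""End-to-end orchestration: run config, staged execution, output manifest.

Stages run in dependency order — reference build, MAPQ recalibration +
assignment per sample, quantification, error profiling, modification-pileup
analysis — each writing into its own subdirectory of the output directory
and never mutating another stage's inputs. The manifest records the package
version, every threshold in effect and a checksum per written table, so a
rerun with the same config is verifiable stage by stage.

Threshold defaults are the canonical analysis values: read quality > 4.0
for counting, pileup min MAPQ 1 / min base quality 2 / depth cap 50 000,
80-event position floor, 100-valid-call site floor, and probability cutoffs
of 0/10/20%.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from nanotrna import __version__
from nanotrna import errors as err
from nanotrna import modsites as mods
from nanotrna import quantify as quant
from nanotrna.alignment import process_alignments
from nanotrna.reference import (
    build_padded_reference,
    deduplicate,
    load_sprinzl,
    parse_gene_set,
    write_reference_fasta,
    write_sprinzl_table,
    write_uniques_table,
)

logger = logging.getLogger(__name__)


class ConfigError(Exception):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataError(Exception):
    """Malformed or inconsistent input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    gene_fasta: str = ""
    annotation: str = ""
    adapter5: str = ""
    adapter3: str = ""
    # sample sheet columns: sample_id, condition, replicate, treated
    sample_sheet: str = ""
    bams: dict[str, str] = field(default_factory=dict)  # sample_id → path
    bedmethyls: dict[str, str] = field(default_factory=dict)
    orthogonal: str = ""  # TSV: trna, sprinzl, rate
    orthogonal_min_rate: float = 0.0
    control_condition: str = "ctrl"
    experimental_condition: str = "exp"
    min_read_qual: float = quant.DEFAULT_MIN_READ_QUAL
    min_mapq: int = err.DEFAULT_MIN_MAPQ
    min_baseq: int = err.DEFAULT_MIN_BASEQ
    max_depth: int = err.DEFAULT_MAX_DEPTH
    min_events: int = err.DEFAULT_MIN_EVENTS
    min_valid_calls: int = mods.DEFAULT_MIN_VALID
    cutoffs: tuple[float, ...] = mods.DEFAULT_CUTOFFS
    fixed_sum: float = quant.DEFAULT_FIXED_SUM
    include_same_target: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(raw["cutoffs"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.gene_fasta or not self.annotation:
            raise ConfigError("gene_fasta and annotation are required")
        for name in ("gene_fasta", "annotation"):
            if not Path(getattr(self, name)).exists():
                raise ConfigError(f"{name} not found: {getattr(self, name)}")
        if self.bedmethyls and not self.sample_sheet:
            raise ConfigError(
                "a sample sheet is required for modification-pileup analysis"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all configured stages; returns (and writes) the manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(frame: pd.DataFrame, relpath: str) -> Path:
        path = out / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, sep="\t", index=True)
        written.append(path)
        return path

    # stage 1: reference ---------------------------------------------------
    try:
        genes = parse_gene_set(config.gene_fasta, config.annotation)
        uniques = deduplicate(genes)
        padded = build_padded_reference(
            uniques, config.adapter5, config.adapter3
        )
        sprinzl = load_sprinzl(genes, uniques)
    except (ValueError, KeyError) as exc:
        raise DataError(f"reference stage: {exc}") from exc
    ref_dir = out / "reference"
    ref_dir.mkdir(exist_ok=True)
    write_reference_fasta(padded, ref_dir / "reference.fasta")
    write_uniques_table(uniques, ref_dir / "uniques.tsv")
    write_sprinzl_table(sprinzl, ref_dir / "sprinzl.tsv")
    written += [
        ref_dir / "reference.fasta",
        ref_dir / "uniques.tsv",
        ref_dir / "sprinzl.tsv",
    ]
    anticodon_lookup = {u.seq_id: u.anticodon_label for u in uniques}
    ref_seqs = {p.seq_id: p.padded_sequence for p in padded}
    body_offsets = {p.seq_id: p.pad5_len for p in padded}
    body_lengths = {p.seq_id: p.body_length for p in padded}
    logger.info(
        "reference: %d genes -> %d unique sequences, %d isoacceptors",
        len(genes),
        len(uniques),
        len({u.anticodon_label for u in uniques}),
    )

    sample_sheet = (
        pd.read_csv(config.sample_sheet, sep="\t")
        if config.sample_sheet
        else None
    )

    # stage 2+3: recalibration, assignment, quantification ----------------
    bins_by_sample: dict[str, pd.DataFrame] = {}
    qc_rows = []
    assignments_by_sample: dict[str, pd.DataFrame] = {}
    if config.bams:
        (out / "recal").mkdir(exist_ok=True)
    for sample_id, bam in config.bams.items():
        try:
            assignments = process_alignments(
                bam,
                anticodon_lookup,
                bam_out=out / "recal" / f"{sample_id}.recal.sam",
                assignments_out=None,
            )
        except (OSError, ValueError, KeyError) as exc:
            raise DataError(f"recalibration stage ({sample_id}): {exc}") from exc
        assignments_by_sample[sample_id] = assignments
        save(assignments, f"recal/{sample_id}.assignments.tsv")
        bins_by_sample[sample_id] = quant.count_per_mapq_bin(
            assignments, min_read_qual=config.min_read_qual
        )
        save(bins_by_sample[sample_id], f"quant/{sample_id}.mapq_bins.tsv")
        qc_rows.append(quant.mapping_qc(assignments, sample_id))

    matrix = None
    if bins_by_sample:
        matrix = quant.expression_matrix(
            bins_by_sample, include_same_target=config.include_same_target
        )
        normalized = quant.normalize_fixed_sum(matrix, config.fixed_sum)
        save(matrix, "quant/counts_raw.tsv")
        save(normalized, "quant/counts_norm1000.tsv")
        save(quant.mapping_qc_frame(qc_rows), "quant/mapping_qc.tsv")

    # stage 4: error profiles ---------------------------------------------
    profiles_by_condition: dict[str, list[pd.DataFrame]] = {}
    if config.bams and sample_sheet is not None:
        cond_of = dict(
            zip(sample_sheet["sample_id"], sample_sheet["condition"])
        )
        for sample_id in config.bams:
            pileups = err.build_pileup(
                out / "recal" / f"{sample_id}.recal.sam",
                ref_seqs,
                min_mapq=config.min_mapq,
                min_baseq=config.min_baseq,
                max_depth=config.max_depth,
            )
            profile = err.error_profile(
                pileups,
                min_events=config.min_events,
                body_offsets=body_offsets,
                body_lengths=body_lengths,
            )
            save(profile, f"errors/{sample_id}.profile.tsv")
            cond = cond_of.get(sample_id, "unknown")
            profiles_by_condition.setdefault(cond, []).append(profile)
        exp = profiles_by_condition.get(config.experimental_condition)
        ctrl = profiles_by_condition.get(config.control_condition)
        if exp and ctrl:
            ratios = err.condition_log2_ratio(exp, ctrl)
            save(ratios, "errors/log2_ratios.tsv")
            tests = err.global_position_test(
                {
                    config.experimental_condition: exp,
                    config.control_condition: ctrl,
                },
                sprinzl,
            )
            save(tests, "errors/position_tests.tsv")

    # stage 5: modification pileups ---------------------------------------
    if config.bedmethyls:
        assert sample_sheet is not None  # enforced by validate()
        records_by_sample = {}
        for sample_id, path in config.bedmethyls.items():
            try:
                parsed = mods.parse_bedmethyl(path)
            except ValueError as exc:
                raise DataError(f"mods stage ({sample_id}): {exc}") from exc
            records_by_sample[sample_id] = mods.filter_records(
                parsed, ref_seqs, min_valid=config.min_valid_calls
            )
        untreated = [
            s
            for s, treated in zip(
                sample_sheet["sample_id"], sample_sheet["treated"]
            )
            if not treated and s in records_by_sample
        ]
        sites = mods.average_sites(records_by_sample, untreated or None)
        sites = mods.annotate_sites(
            sites, sprinzl, body_offsets, anticodon_lookup
        )
        save(mods.sites_frame(sites), "mods/sites_mean.tsv")
        rolled = mods.rollup_anticodon(sites)
        for cutoff in config.cutoffs:
            kept = mods.threshold_sites(rolled, cutoff)
            save(
                mods.sites_frame(kept),
                f"mods/sites_gt{int(cutoff)}pct.tsv",
            )
        hm = mods.heatmap_matrix(mods.threshold_sites(rolled, 10.0))
        if not hm.empty:
            save(hm, "mods/heatmap_gt10pct.tsv")
        if config.orthogonal:
            ortho = pd.read_csv(config.orthogonal, sep="\t")
            comparison = mods.compare_orthogonal(
                mods.threshold_sites(rolled, 10.0),
                ortho,
                min_orthogonal_rate=config.orthogonal_min_rate,
            )
            comp_path = out / "mods" / "orthogonal_comparison.json"
            comp_path.write_text(
                json.dumps(
                    {
                        "n_shared": comparison.n_shared,
                        "n_left_only": comparison.n_left_only,
                        "n_right_only": comparison.n_right_only,
                        "shared": comparison.shared,
                        "left_only": comparison.left_only,
                        "right_only": comparison.right_only,
                        "unmapped_right": comparison.unmapped_right,
                    },
                    indent=2,
                )
            )
            written.append(comp_path)

    manifest = {
        "version": __version__,
        "thresholds": {
            "min_read_qual": config.min_read_qual,
            "min_mapq": config.min_mapq,
            "min_baseq": config.min_baseq,
            "max_depth": config.max_depth,
            "min_events": config.min_events,
            "min_valid_calls": config.min_valid_calls,
            "cutoffs": list(config.cutoffs),
            "fixed_sum": config.fixed_sum,
            "include_same_target": config.include_same_target,
        },
        "inputs": {
            "gene_fasta": _sha256(Path(config.gene_fasta)),
            "annotation": _sha256(Path(config.annotation)),
        },
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(written)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
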