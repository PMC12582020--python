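"""Pileup counting, error statistics, condition ratios and position tests."""

import math

import numpy as np
import pandas as pd
import pysam
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from nanotrna import errors as err
from nanotrna.errors import (
    PositionPileup,
    bh_adjust,
    build_pileup,
    condition_log2_ratio,
    global_position_test,
    ref_base_fraction,
    relative_error,
    site_error_report,
    welch_t,
)
from nanotrna.reference import SprinzlAnnotation


def pileup(ref="C", A=0, C=0, G=0, T=0, deletion=0, insertion=0):
    return PositionPileup(
        "t1",
        0,
        ref,
        {"A": A, "C": C, "G": G, "T": T,
         "deletion": deletion, "insertion": insertion},
    )


class TestErrorStatistics:
    def test_relative_error_formula(self):
        # 80 matches, 10 mismatches, 10 deletions; insertions excluded
        p = pileup(C=80, A=10, deletion=10, insertion=50)
        assert relative_error(p) == pytest.approx(0.2)
        assert p.total_events == 100

    def test_all_match_and_all_deletion(self):
        assert relative_error(pileup(C=50)) == 0.0
        assert relative_error(pileup(deletion=7)) == 1.0

    def test_ref_base_fraction(self):
        p = pileup(C=90, G=5, deletion=5)
        assert ref_base_fraction(p) == pytest.approx(0.9)

    def test_empty_pileup_returns_absent(self):
        assert relative_error(pileup()) is None
        assert ref_base_fraction(pileup()) is None

    @settings(max_examples=300, deadline=None)
    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
    )
    def test_complement_identity(self, a, c, g, t, dele, ins):
        """relative_error + ref_base_fraction = 1 exactly: complementary
        numerators over the same denominator."""
        p = pileup(A=a, C=c, G=g, T=t, deletion=dele, insertion=ins)
        if p.total_events == 0:
            return
        assert relative_error(p) + ref_base_fraction(p) == pytest.approx(
            1.0, abs=1e-12
        )


def write_sam(path, reference, reads):
    """reads: list of (name, flag, pos, mapq, cigartuples, seq, qual)."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "t1", "LN": len(reference)}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, flag, pos, mapq, cigar, seq, qual in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                chr(qual + 33) * len(seq)
            )
            a.cigartuples = cigar
            a.set_tag("AS", len(seq))
            out.write(a)


class TestBuildPileup:
    REF = {"t1": "ACGTACGT"}

    def test_perfect_reads(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(
            sam, self.REF["t1"],
            [(f"r{i}", 0, 0, 60, [(0, 8)], "ACGTACGT", 20) for i in range(100)],
        )
        piles = build_pileup(sam, self.REF)
        p = piles["t1"][0]
        assert p.counts["A"] == 100
        assert relative_error(p) == 0.0

    def test_low_baseq_calls_excluded(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(
            sam, self.REF["t1"],
            [("r0", 0, 0, 60, [(0, 8)], "ACGTACGT", 1),
             ("r1", 0, 0, 60, [(0, 8)], "ACGTACGT", 20)],
        )
        piles = build_pileup(sam, self.REF, min_baseq=2)
        assert piles["t1"][0].total_events == 1

    def test_low_mapq_reads_excluded(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(
            sam, self.REF["t1"],
            [("r0", 0, 0, 0, [(0, 8)], "ACGTACGT", 20),
             ("r1", 0, 0, 1, [(0, 8)], "ACGTACGT", 20)],
        )
        piles = build_pileup(sam, self.REF, min_mapq=1)
        assert piles["t1"][0].total_events == 1

    def test_deletions_counted_at_each_deleted_position(self, tmp_path):
        sam = tmp_path / "a.sam"
        # 3M2D3M: positions 3 and 4 deleted
        write_sam(
            sam, self.REF["t1"],
            [("r0", 0, 0, 60, [(0, 3), (2, 2), (0, 3)], "ACGCGT", 20)],
        )
        piles = build_pileup(sam, self.REF)
        assert piles["t1"][3].counts["deletion"] == 1
        assert piles["t1"][4].counts["deletion"] == 1

    def test_insertions_tracked_left_not_events(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(
            sam, self.REF["t1"],
            [("r0", 0, 0, 60, [(0, 4), (1, 2), (0, 4)], "ACGTTTACGT", 20)],
        )
        piles = build_pileup(sam, self.REF)
        assert piles["t1"][3].counts["insertion"] == 2
        assert piles["t1"][3].total_events == 1

    def test_depth_cap_first_come(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(
            sam, self.REF["t1"],
            [(f"r{i}", 0, 0, 60, [(0, 8)], "ACGTACGT", 20) for i in range(30)],
        )
        piles = build_pileup(sam, self.REF, max_depth=10)
        assert piles["t1"][0].total_events == 10

    def test_unknown_contig_is_hard_error(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(
            sam, self.REF["t1"],
            [("r0", 0, 0, 60, [(0, 8)], "ACGTACGT", 20)],
        )
        with pytest.raises(KeyError):
            build_pileup(sam, {"other": "ACGT"})

    def test_planted_mismatch_fraction_recovered(self, sim_dataset):
        simulator, manifest, _ = sim_dataset
        from nanotrna.alignment import process_alignments

        lookup = {u.seq_id: u.anticodon_label for u in simulator.uniques}
        sample = manifest["samples"][0]  # control condition
        ref = {p.seq_id: p.padded_sequence for p in simulator.padded}
        recal = manifest["samples"][0]["sam"] + ".recal"
        process_alignments(sample["sam"], lookup, bam_out=recal)
        piles = build_pileup(recal, ref)
        offsets = {p.seq_id: p.pad5_len for p in simulator.padded}
        lengths = {p.seq_id: p.body_length for p in simulator.padded}
        profile = err.error_profile(piles, 80, offsets, lengths)
        planted = simulator.config.baseline_error_rate
        # forced-deletion multi-mapping reads add a small excess at a few
        # positions; the profile-wide mean tracks the planted baseline
        observed = profile["relative_error"].mean()
        assert abs(observed - planted) < 0.02


class TestEventFilter:
    def test_positions_below_min_events_absent(self):
        piles = {
            "t1": {
                0: pileup(C=100),
                1: pileup(C=79),
            }
        }
        piles["t1"][1].seq_id = "t1"
        prof = err.error_profile(piles, min_events=80)
        assert list(prof["position"]) == [0]


class TestConditionLog2Ratio:
    def prof(self, errors):
        return pd.DataFrame(
            {
                "seq_id": ["t1"] * len(errors),
                "position": range(len(errors)),
                "ref_base": ["C"] * len(errors),
                "relative_error": errors,
                "ref_base_fraction": [1 - e for e in errors],
                "total_events": [100] * len(errors),
            }
        )

    def test_fourfold_is_two(self):
        r = condition_log2_ratio([self.prof([0.4])], [self.prof([0.1])])
        assert r["log2_ratio"].iloc[0] == pytest.approx(2.0)

    def test_equal_means_zero(self):
        r = condition_log2_ratio([self.prof([0.3])], [self.prof([0.3])])
        assert r["log2_ratio"].iloc[0] == pytest.approx(0.0)

    def test_zero_control_gives_sentinel(self):
        r = condition_log2_ratio([self.prof([0.2])], [self.prof([0.0])])
        assert math.isinf(r["log2_ratio"].iloc[0])

    def test_pseudocount_option(self):
        r = condition_log2_ratio(
            [self.prof([0.2])], [self.prof([0.0])], pseudocount=0.01
        )
        assert math.isfinite(r["log2_ratio"].iloc[0])

    def test_intersection_of_replicate_positions(self):
        exp = [self.prof([0.1, 0.2]), self.prof([0.1])]
        ctrl = [self.prof([0.1, 0.1])]
        r = condition_log2_ratio(exp, ctrl)
        # position 1 missing from one experimental replicate: dropped
        assert list(r["position"]) == [0]


class TestWelchAndBH:
    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_welch_matches_scipy(self, data):
        a = data.draw(
            st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=12)
        )
        b = data.draw(
            st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=12)
        )
        # degenerate / denormal-variance draws are excluded: there scipy's
        # df formula underflows (falling back to df=1) while the normalized
        # Satterthwaite form stays exact, so the two legitimately differ
        if np.var(a, ddof=1) < 1e-30 or np.var(b, ddof=1) < 1e-30:
            return
        t, p, df = welch_t(a, b)
        ref = scipy.stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_pooled_matches_scipy(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=8)
        t, p, df = welch_t(a, b, equal_var=True)
        ref = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
        assert df == 16

    def test_degenerate_identical_groups(self):
        t, p, _ = welch_t([0.5, 0.5], [0.5, 0.5])
        assert (t, p) == (0.0, 1.0)

    def test_bh_closed_form(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adj, ref, atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()


class TestGlobalPositionTest:
    def make_profiles(self, rng, shift=0.0):
        rows = []
        for seq in ("a", "b", "c", "d"):
            for pos in range(5):
                rows.append(
                    {
                        "seq_id": seq,
                        "position": pos,
                        "ref_base": "C",
                        "relative_error": float(
                            np.clip(rng.normal(0.05 + shift, 0.01), 0, 1)
                        ),
                        "ref_base_fraction": 0.9,
                        "total_events": 100,
                    }
                )
        return pd.DataFrame(rows)

    @pytest.fixture()
    def sprinzl(self):
        labels = [str(i + 1) for i in range(5)]
        return {s: SprinzlAnnotation(s, labels) for s in "abcd"}

    def test_shifted_condition_detected(self, sprinzl, rng):
        exp = [self.make_profiles(rng, shift=0.2) for _ in range(2)]
        ctrl = [self.make_profiles(rng) for _ in range(2)]
        res = global_position_test({"exp": exp, "ctrl": ctrl}, sprinzl)
        assert len(res) == 5
        assert (res["padj"] < 0.05).all()
        assert (res["padj"] >= res["pvalue"] - 1e-15).all()

    def test_identical_groups_null(self, sprinzl, rng):
        prof = self.make_profiles(rng)
        res = global_position_test(
            {"exp": [prof], "ctrl": [prof.copy()]}, sprinzl
        )
        assert (res["t"] == 0).all()
        assert (res["pvalue"] == 1.0).all()

    def test_requires_two_conditions(self, sprinzl, rng):
        with pytest.raises(ValueError):
            global_position_test({"only": [self.make_profiles(rng)]}, sprinzl)


class TestSiteErrorReport:
    def prof(self, e36, e37, e38):
        return pd.DataFrame(
            {
                "seq_id": ["phe"] * 3,
                "position": [35, 36, 37],
                "ref_base": ["A", "G", "A"],
                "relative_error": [e36, e37, e38],
                "ref_base_fraction": [1 - e36, 1 - e37, 1 - e38],
                "total_events": [500] * 3,
            }
        )

    @pytest.fixture()
    def sprinzl(self):
        return {"phe": SprinzlAnnotation("phe", [str(i + 1) for i in range(40)])}

    def test_mean_and_sd(self, sprinzl):
        rep = site_error_report(
            {"high": [self.prof(0.1, 0.2, 0.1), self.prof(0.1, 0.4, 0.1)]},
            "phe",
            ["37"],
            sprinzl,
        )
        assert rep["mean_error"].iloc[0] == pytest.approx(0.3)
        assert rep["sd_error"].iloc[0] == pytest.approx(
            np.std([0.2, 0.4], ddof=1)
        )

    def test_single_replicate_sd_absent(self, sprinzl):
        rep = site_error_report(
            {"c": [self.prof(0.1, 0.2, 0.1)]}, "phe", ["37"], sprinzl
        )
        assert math.isnan(rep["sd_error"].iloc[0])

    def test_unresolvable_label_gives_absent_row(self, sprinzl):
        rep = site_error_report(
            {"c": [self.prof(0.1, 0.2, 0.1)]}, "phe", ["e11"], sprinzl
        )
        assert rep["n_replicates"].iloc[0] == 0
        assert math.isnan(rep["mean_error"].iloc[0])
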