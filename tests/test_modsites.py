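"""bedMethyl parsing, filtering, averaging, thresholds, set comparison."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanotrna.modsites import (
    ModPileupRecord,
    ModSite,
    annotate_sites,
    average_sites,
    compare_orthogonal,
    filter_records,
    heatmap_matrix,
    parse_bedmethyl,
    rollup_anticodon,
    threshold_sites,
    write_bedmethyl,
)
from nanotrna.reference import SprinzlAnnotation


def record(seq="t1", pos=10, strand="+", code="m", n_valid=200, n_mod=50):
    return ModPileupRecord(
        seq_id=seq,
        position=pos,
        strand=strand,
        mod_code=code,
        n_valid=n_valid,
        n_mod=n_mod,
        n_canonical=n_valid - n_mod,
    )


def site(seq="t1", pos=10, code="m", frac=0.5, sprinzl=None, anticodon=None):
    return ModSite(
        seq_id=seq,
        position=pos,
        mod_code=code,
        mean_fraction=frac,
        n_samples=2,
        sprinzl=sprinzl,
        anticodon=anticodon,
    )


class TestParseBedmethyl:
    def test_round_trip(self, tmp_path):
        records = [
            record(pos=5, n_valid=150, n_mod=30),
            record(pos=9, code="17802", n_valid=120, n_mod=110),
            record(pos=12, code="a", strand="-", n_valid=99, n_mod=0),
        ]
        path = tmp_path / "x.bedmethyl"
        write_bedmethyl(records, path)
        back = parse_bedmethyl(path)
        assert back == records
        write_bedmethyl(back, tmp_path / "y.bedmethyl")
        assert (tmp_path / "y.bedmethyl").read_bytes() == path.read_bytes()

    def test_fraction_consistent_with_counts(self, tmp_path):
        path = tmp_path / "x.bedmethyl"
        write_bedmethyl([record(n_valid=400, n_mod=100)], path)
        rec = parse_bedmethyl(path)[0]
        assert rec.fraction_modified == pytest.approx(
            rec.n_mod / rec.n_valid, abs=1e-6
        )

    def test_nmod_exceeding_nvalid_is_an_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            record(n_valid=10, n_mod=11)

    def test_malformed_line_names_the_line(self, tmp_path):
        path = tmp_path / "bad.bedmethyl"
        path.write_text("t1\t5\t6\tm\n")
        with pytest.raises(ValueError, match="bad.bedmethyl:1"):
            parse_bedmethyl(path)

    def test_unknown_code_skipped_with_warning(self, tmp_path):
        path = tmp_path / "x.bedmethyl"
        write_bedmethyl([record()], path)
        line = path.read_text().replace("\tm\t", "\tz\t")
        path.write_text(line)
        with pytest.warns(UserWarning, match="unknown modification code"):
            assert parse_bedmethyl(path) == []


class TestFilterRecords:
    REF = {"t1": "A" * 10 + "C" + "A" * 9}  # C at position 10

    def test_keeps_valid_plus_strand_matching_base(self):
        assert filter_records([record()], self.REF) == [record()]

    def test_minus_strand_excluded(self):
        assert filter_records([record(strand="-")], self.REF) == []

    def test_min_valid_is_inclusive_floor(self):
        kept = filter_records(
            [record(n_valid=99, n_mod=0), record(n_valid=100, n_mod=0)],
            self.REF,
        )
        assert [r.n_valid for r in kept] == [100]

    def test_reference_base_mismatch_excluded(self):
        # m5C called where the reference base is A
        assert filter_records([record(pos=0)], self.REF) == []

    def test_idempotent_and_order_independent(self):
        records = [
            record(), record(strand="-"), record(n_valid=50, n_mod=10),
            record(pos=3),
        ]
        once = filter_records(records, self.REF)
        assert filter_records(once, self.REF) == once
        assert sorted(
            filter_records(records[::-1], self.REF),
            key=lambda r: r.position,
        ) == sorted(once, key=lambda r: r.position)


class TestAverageSites:
    def test_mean_over_samples(self):
        by_sample = {
            "s1": [record(n_valid=100, n_mod=20)],
            "s2": [record(n_valid=100, n_mod=40)],
        }
        sites = average_sites(by_sample)
        assert sites[0].mean_fraction == pytest.approx(0.3)
        assert sites[0].n_samples == 2

    def test_absent_sample_contributes_no_term(self):
        by_sample = {
            "s1": [record(n_valid=100, n_mod=20)],
            "s2": [],
        }
        sites = average_sites(by_sample)
        assert sites[0].mean_fraction == pytest.approx(0.2)
        assert sites[0].n_samples == 1

    def test_sample_subset_respected(self):
        by_sample = {
            "untreated": [record(n_valid=100, n_mod=20)],
            "treated": [record(n_valid=100, n_mod=90)],
        }
        sites = average_sites(by_sample, include_samples=["untreated"])
        assert sites[0].mean_fraction == pytest.approx(0.2)


class TestThresholdSites:
    def test_strict_inequality_at_cutoff(self):
        sites = [site(frac=0.10), site(pos=11, frac=0.101)]
        kept = threshold_sites(sites, 10.0)
        assert [s.position for s in kept] == [11]

    def test_zero_cutoff_keeps_any_modified(self):
        sites = [site(frac=0.0), site(pos=11, frac=0.001)]
        assert [s.position for s in threshold_sites(sites, 0.0)] == [11]

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(0, 1, allow_nan=False), min_size=0, max_size=30
        )
    )
    def test_threshold_nesting(self, fracs):
        sites = [site(pos=i, frac=f) for i, f in enumerate(fracs)]
        s20 = {x.position for x in threshold_sites(sites, 20.0)}
        s10 = {x.position for x in threshold_sites(sites, 10.0)}
        s0 = {x.position for x in threshold_sites(sites, 0.0)}
        assert s20 <= s10 <= s0


class TestAnnotateAndRollup:
    def test_annotation_attaches_labels(self):
        ann = {"t1": SprinzlAnnotation("t1", [str(i + 1) for i in range(20)])}
        sites = annotate_sites(
            [site(pos=14)], ann, body_offsets={"t1": 5},
            anticodon_lookup={"t1": "Gly-GCC"},
        )
        assert sites[0].sprinzl == "10"
        assert sites[0].anticodon == "Gly-GCC"

    def test_pad_positions_unlabelled(self):
        ann = {"t1": SprinzlAnnotation("t1", ["1", "2"])}
        sites = annotate_sites([site(pos=1)], ann, body_offsets={"t1": 5})
        assert sites[0].sprinzl is None

    def test_rollup_takes_max_over_isodecoders(self):
        sites = [
            site(seq="t1", frac=0.2, sprinzl="48", anticodon="Gly-GCC"),
            site(seq="t2", frac=0.6, sprinzl="48", anticodon="Gly-GCC"),
        ]
        rolled = rollup_anticodon(sites)
        assert len(rolled) == 1
        assert rolled[0].mean_fraction == pytest.approx(0.6)

    def test_heatmap_matrix_shape(self):
        sites = [
            site(frac=0.5, sprinzl="48", anticodon="Gly-GCC"),
            site(pos=20, frac=0.3, sprinzl="55", anticodon="Gly-GCC"),
            site(seq="t2", frac=0.9, sprinzl="48", anticodon="Asp-GTC"),
        ]
        hm = heatmap_matrix(sites)
        assert hm.shape == (2, 2)
        assert hm.loc["Gly-GCC", "48"] == pytest.approx(50.0)


class TestCompareOrthogonal:
    def ortho(self, rows):
        return pd.DataFrame(rows, columns=["trna", "sprinzl", "rate"])

    def nano(self, keys):
        return [
            site(frac=0.5, sprinzl=lab, anticodon=trna) for trna, lab in keys
        ]

    def test_overlap_counts(self):
        left = self.nano([("Gly-GCC", "48"), ("Gly-GCC", "49"), ("Asp-GTC", "48")])
        right = self.ortho(
            [("Gly-GCC", "49", 80.0), ("Asp-GTC", "48", 60.0),
             ("Cys-GCA", "48", 70.0)]
        )
        c = compare_orthogonal(left, right)
        assert (c.n_shared, c.n_left_only, c.n_right_only) == (2, 1, 1)
        assert c.n_shared + c.n_left_only == len({
            (s.anticodon, s.sprinzl) for s in left
        })

    def test_disjoint_sets(self):
        c = compare_orthogonal(
            self.nano([("Gly-GCC", "48")]),
            self.ortho([("Asp-GTC", "55", 50.0)]),
        )
        assert c.n_shared == 0

    def test_orthogonal_rate_prefilter_strict(self):
        right = self.ortho(
            [("Gly-GCC", "48", 10.0), ("Asp-GTC", "48", 10.1)]
        )
        c = compare_orthogonal(self.nano([]), right, min_orthogonal_rate=10.0)
        assert c.n_right_only == 1

    def test_unmappable_orthogonal_rows_reported(self):
        right = self.ortho([("Xyz-NNN", "48", 50.0)])
        c = compare_orthogonal(
            self.nano([]), right, known_trnas={"Gly-GCC"}
        )
        assert c.unmapped_right == [("Xyz-NNN", "48")]
        assert c.n_right_only == 0

    def test_isodecoder_key_level(self):
        left = [site(seq="t1", frac=0.5, sprinzl="48", anticodon="Gly-GCC")]
        right = self.ortho([("t1", "48", 50.0)])
        c = compare_orthogonal(left, right, key="isodecoder")
        assert c.n_shared == 1
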