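import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sangerase.errors import (
    AmbiguityError,
    GeneLookupError,
    ParameterError,
    RepeatMaskerParseError,
)
from sangerase.locus_architecture import (
    GeneInterval,
    compute_cpg_density,
    compute_gene_gap,
    join_divergence,
    parse_gene_intervals,
    repeat_class_of,
    summarize_repeats,
)

RM_HEADER = (
    "   SW  perc perc perc  query    position in query  matching repeat  pos\n"
    "score  div. del. ins.  sequence begin end (left) repeat class/family "
    "begin end (left) ID\n"
    "\n"
)


def iv(gene_id, start, end, seq_id="chr1", strand="+"):
    return GeneInterval(gene_id, seq_id, start, end, strand)


class TestGeneIntervals:
    def test_parse_from_gff3(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1000\t11000\t.\t+\t.\tID=TH;Name=TH\n"
            "chr1\tsrc\tgene\t13400\t14000\t.\t+\t.\tID=INS;Name=INS\n"
        )
        th, ins = parse_gene_intervals(str(p), ["TH", "INS"])
        assert (th.start, th.end) == (1000, 11000)
        assert (ins.start, ins.end) == (13400, 14000)

    def test_absent_gene_raises_lookup_error(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text("##gff-version 3\nchr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=TH\n")
        with pytest.raises(GeneLookupError, match="INS"):
            parse_gene_intervals(str(p), ["INS"])

    def test_duplicate_gene_id_is_ambiguous(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=TH_a;Name=TH\n"
            "chr1\tsrc\tgene\t50\t60\t.\t+\t.\tID=TH_b;Name=TH\n"
        )
        with pytest.raises(AmbiguityError):
            parse_gene_intervals(str(p), ["TH"])


class TestGeneGap:
    def test_unlinked_on_different_sequences(self):
        rec = compute_gene_gap(
            iv("th", 100, 200, seq_id="chr25"), iv("ins", 100, 200, seq_id="chr5")
        )
        assert not rec.linked
        assert rec.gap_bp is None

    def test_simple_gap(self):
        rec = compute_gene_gap(iv("TH", 1000, 10000), iv("INS", 12400, 14000))
        assert rec.linked and rec.gap_bp == 2400 and not rec.overlap

    def test_overlap_is_negative_and_flagged(self):
        rec = compute_gene_gap(iv("A", 100, 500), iv("B", 400, 900))
        assert rec.gap_bp == -100
        assert rec.overlap

    @given(
        a_start=st.integers(1, 10_000),
        a_len=st.integers(0, 5_000),
        b_start=st.integers(1, 10_000),
        b_len=st.integers(0, 5_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetric_under_argument_swap(self, a_start, a_len, b_start, b_len):
        a = iv("A", a_start, a_start + a_len)
        b = iv("B", b_start, b_start + b_len)
        r1 = compute_gene_gap(a, b)
        r2 = compute_gene_gap(b, a)
        assert (r1.gap_bp, r1.linked, r1.overlap) == (r2.gap_bp, r2.linked, r2.overlap)


class TestRepeatSummary:
    def test_single_hit_percentage(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(
            RM_HEADER
            + " 1000 10.0 1.0 1.0 chr1 20001 50000 (50000) + MERV LTR/ERVK 1 30000 (0) 1\n"
        )
        s = summarize_repeats(str(p), ("chr1", 1, 100_000))
        assert s.per_class["LTR"] == (30_000, 30.0)
        assert s.per_element["MERV"] == 30_000

    def test_empty_out_gives_all_zero(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(RM_HEADER)
        s = summarize_repeats(str(p), ("chr1", 1, 1000))
        assert all(bp == 0 and pct == 0.0 for bp, pct in s.per_class.values())

    def test_overlapping_hits_merged_once(self, tmp_path):
        line = " 1000 10.0 1.0 1.0 chr1 100 200 (0) + L1 LINE/L1 1 101 (0) 1\n"
        p = tmp_path / "rm.out"
        p.write_text(RM_HEADER + line + line)
        s = summarize_repeats(str(p), ("chr1", 1, 1000))
        assert s.per_class["LINE"][0] == 101
        # per-element totals are raw clipped lengths, so they double-count
        assert s.per_element["L1"] == 202

    def test_row_order_invariance(self, tmp_path):
        l1 = " 1000 10.0 1.0 1.0 chr1 100 200 (0) + L1 LINE/L1 1 101 (0) 1\n"
        l2 = " 1000 10.0 1.0 1.0 chr1 150 400 (0) + L2 LINE/L1 1 251 (0) 2\n"
        p1, p2 = tmp_path / "a.out", tmp_path / "b.out"
        p1.write_text(RM_HEADER + l1 + l2)
        p2.write_text(RM_HEADER + l2 + l1)
        s1 = summarize_repeats(str(p1), ("chr1", 1, 1000))
        s2 = summarize_repeats(str(p2), ("chr1", 1, 1000))
        assert s1.per_class == s2.per_class

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(RM_HEADER + "garbage line\n")
        with pytest.raises(RepeatMaskerParseError) as err:
            summarize_repeats(str(p), ("chr1", 1, 1000))
        assert err.value.lineno == 4

    def test_class_mapping(self):
        assert repeat_class_of("LTR/ERVK") == "LTR"
        assert repeat_class_of("Simple_repeat") == "Simple_repeat"
        assert repeat_class_of("rRNA") == "Other"


class TestCpGDensity:
    def test_no_cg_gives_zero(self):
        track = compute_cpg_density("A" * 100, 10)
        assert track.values == [0.0] * 10

    def test_cgcg_single_window(self):
        assert compute_cpg_density("CGCG", 4).values == [50.0]

    def test_all_n_window_is_zero(self):
        assert compute_cpg_density("N" * 10, 10).values == [0.0]

    def test_partial_final_window_normalized_by_own_length(self):
        # 6 bases + 2-base tail "CG" -> final window density 100*1/2
        track = compute_cpg_density("AAAAAACG", 6)
        assert track.values == [0.0, 50.0]

    def test_window_too_small_rejected(self):
        with pytest.raises(ParameterError):
            compute_cpg_density("ACGT", 1)

    @given(st.text(alphabet="ACGT", min_size=4, max_size=64))
    @settings(max_examples=100, deadline=None)
    def test_reverse_complement_symmetry_full_window(self, seq):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        fwd = compute_cpg_density(seq, len(seq)).values
        rev = compute_cpg_density(rc, len(seq)).values
        assert fwd == pytest.approx(rev)


class TestJoinDivergence:
    def make_records(self):
        return [
            compute_gene_gap(iv("TH", 1, 10), iv("INS", 50, 60), species=sp)
            for sp in ("mouse", "rat", "wallaby")
        ]

    def test_left_join_and_sort(self, tmp_path):
        p = tmp_path / "div.tsv"
        p.write_text("species\tmya\nMouse\t0\nRat\t13\n")
        out = join_divergence(self.make_records(), str(p))
        assert list(out["species"]) == ["mouse", "rat", "wallaby"]
        assert out.loc[out.species == "rat", "divergence_mya"].iloc[0] == 13
        assert out["divergence_mya"].isna().iloc[-1]

    def test_duplicate_species_is_ambiguous(self, tmp_path):
        p = tmp_path / "div.tsv"
        p.write_text("species\tmya\nmouse\t0\nMOUSE\t1\n")
        with pytest.raises(AmbiguityError):
            join_divergence(self.make_records(), str(p))
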