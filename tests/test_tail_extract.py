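"""Tail derivation, classification, filters, UMI dedup and G-tail parsing."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tailscape.io_formats import AlignedRead, GeneModel, TailRecord
from tailscape.tail_extract import (
    FALSE_SCORE_12PLUS,
    HIGH_TCG,
    TRUE,
    assign_gene,
    classify_tail,
    dedup_umi,
    extract_candidate_tail,
    filter_polya_plus,
    flam_split_gi_tail,
    last_exon_filter,
    transition_score,
)

nucleotides = st.text(alphabet="ACGTN", min_size=0, max_size=200)


def _read(strand="+", clip5="", clip3="", start=100, end=200, **kw):
    defaults = dict(
        read_id="r1", barcode="bc", pass_count=12, chrom="c1",
        strand=strand, aln_start=start, aln_end=end, clip5=clip5, clip3=clip3,
    )
    defaults.update(kw)
    return AlignedRead(**defaults)


class TestExtractCandidateTail:
    def test_plus_strand_uses_clip3(self):
        assert extract_candidate_tail(_read("+", clip3="AAAAA")) == "AAAAA"

    def test_minus_strand_revcomps_clip5(self):
        assert extract_candidate_tail(_read("-", clip5="TTTTT")) == "AAAAA"
        assert extract_candidate_tail(_read("-", clip5="CTTTT")) == "AAAAG"

    def test_empty_clip_is_zero_nt_tail(self):
        assert extract_candidate_tail(_read("+", clip3="")) == ""


def brute_transition_score(seq):
    return sum(1 for i in range(1, len(seq)) if seq[i] != seq[i - 1])


def brute_classify(seq):
    """Independent re-statement of the classification rules."""
    seq = seq.upper()
    non_n = [c for c in seq if c != "N"]
    if non_n:
        props = {b: non_n.count(b) / len(non_n) for b in "TCG"}
        if all(props[b] >= 0.1 for b in "TCG"):
            return HIGH_TCG
    if brute_transition_score(seq) > 12:
        return FALSE_SCORE_12PLUS
    return TRUE


class TestClassifyTail:
    @pytest.mark.parametrize(
        "seq,score",
        [("", 0), ("A", 0), ("AAAA", 0), ("ATCG", 3), ("AT" * 7, 13)],
    )
    def test_transition_score_examples(self, seq, score):
        assert transition_score(seq) == score

    @pytest.mark.parametrize(
        "seq,label",
        [
            ("TTTCCCGGGA", HIGH_TCG),
            ("ATATATATATATAT", FALSE_SCORE_12PLUS),
            ("AAAAATTAAAAA", TRUE),
            ("AAAAAAAAAA", TRUE),
            ("", TRUE),
        ],
    )
    def test_label_examples(self, seq, label):
        assert classify_tail(seq).label == label

    def test_high_tcg_takes_precedence_over_score(self):
        # alternating TCG has both properties; HIGH_TCG is checked first
        seq = "TCG" * 10
        assert transition_score(seq) > 12
        assert classify_tail(seq).label == HIGH_TCG

    @given(nucleotides)
    def test_agrees_with_bruteforce(self, seq):
        cls = classify_tail(seq)
        assert cls.label == brute_classify(seq)
        assert cls.transition_score == brute_transition_score(seq)

    @given(st.integers(0, 300))
    def test_pure_a_always_true(self, n):
        assert classify_tail("A" * n).label == TRUE

    def test_proportions_exclude_n(self):
        # without N-exclusion the proportions would be 2/8 < ... here
        # T,C,G each 1 of 3 non-N bases -> HIGH_TCG
        assert classify_tail("TCGNNNNN").label == HIGH_TCG


def _tail_record(read_id, pass_count, tail, barcode="bc", gene="gA", umi=None):
    rec = TailRecord(
        barcode=barcode, read_id=read_id, gene_id=gene, pass_count=pass_count,
        count_a=tail.count("A"), count_t=tail.count("T"),
        count_c=tail.count("C"), count_g=tail.count("G"),
        count_nona=tail.count("T") + tail.count("C") + tail.count("G"),
        tail_seq=tail,
    )
    rec.umi = umi
    return rec


class TestPolyAPlusFilter:
    def test_boundary_kept(self):
        assert filter_polya_plus([_tail_record("r", 10, "A")])

    @pytest.mark.parametrize("pc,tail", [(9, "A" * 50), (12, "")])
    def test_below_threshold_dropped(self, pc, tail):
        assert filter_polya_plus([_tail_record("r", pc, tail)]) == []

    def test_subset_and_idempotent(self):
        records = [
            _tail_record(f"r{i}", pc, t)
            for i, (pc, t) in enumerate([(10, "AA"), (3, "AA"), (15, ""), (30, "A")])
        ]
        once = filter_polya_plus(records)
        assert set(r.read_id for r in once) <= set(r.read_id for r in records)
        assert filter_polya_plus(once) == once


class TestDedupUmi:
    def test_highest_pass_wins(self):
        a = _tail_record("r_b", 15, "AAA", umi="ACGT")
        b = _tail_record("r_a", 11, "AAA", umi="ACGT")
        result = dedup_umi([a, b])
        assert result.records == [a]

    def test_pass_tie_smallest_read_id(self):
        a = _tail_record("r_b", 11, "AAA", umi="ACGT")
        b = _tail_record("r_a", 11, "AAA", umi="ACGT")
        assert dedup_umi([a, b]).records == [b]

    def test_distinct_umis_both_kept(self):
        a = _tail_record("r1", 11, "AAA", umi="AAAA")
        b = _tail_record("r2", 11, "AAA", umi="CCCC")
        assert len(dedup_umi([a, b]).records) == 2

    def test_missing_umi_passthrough_counted(self):
        a = _tail_record("r1", 11, "AAA", umi=None)
        result = dedup_umi([a])
        assert result.records == [a]
        assert result.n_missing_umi == 1

    def test_empty_input(self):
        assert dedup_umi([]).records == []

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["u1", "u2", "u3"]),
                st.integers(1, 40),
                st.sampled_from(["gA", "gB"]),
            ),
            max_size=30,
        )
    )
    def test_idempotent_and_keys_unique(self, raw):
        records = [
            _tail_record(f"r{i}", pc, "AAA", gene=g, umi=u)
            for i, (u, pc, g) in enumerate(raw)
        ]
        once = dedup_umi(records).records
        keys = [(r.barcode, r.umi, r.gene_id) for r in once]
        assert len(keys) == len(set(keys))
        assert dedup_umi(once).records == once


class TestLastExonFilter:
    gene = GeneModel("g", "c1", "+", exons=[(1, 100), (201, 300)])

    @pytest.mark.parametrize("end,expected", [(250, True), (150, False), (300, True)])
    def test_plus_strand_containment(self, end, expected):
        read = _read("+", start=end - 40, end=end)
        assert last_exon_filter(read, self.gene) is expected

    def test_minus_strand_uses_aln_start(self):
        gene = GeneModel("g", "c1", "-", exons=[(1, 100), (201, 300)])
        assert last_exon_filter(_read("-", start=50, end=250), gene)
        assert not last_exon_filter(_read("-", start=150, end=250), gene)


class TestFlamGiTail:
    def test_rule_table_over_run_lengths(self):
        prefix = "CCCAAAA"
        for g in range(0, 26):
            out = flam_split_gi_tail(prefix + "G" * g)
            if g < 7:
                assert out is None
            elif g <= 16:
                assert out == prefix
            else:
                assert out == prefix + "G" * (g - 17)

    def test_all_g_segment(self):
        assert flam_split_gi_tail("G" * 10) == ""


class TestAssignGene:
    genes = [
        GeneModel("gA", "c1", "+", exons=[(100, 400)]),
        GeneModel("gB", "c1", "+", exons=[(350, 700)]),
        GeneModel("gC", "c1", "-", exons=[(900, 1200)]),
    ]

    def test_unique_containment(self):
        read = _read("+", start=150, end=300)
        assert assign_gene(read, self.genes) == "gA"

    def test_ambiguous_overlap_is_none(self):
        read = _read("+", start=300, end=500)
        assert assign_gene(read, self.genes) is None

    def test_strand_mismatch_is_none(self):
        read = _read("+", start=950, end=1100)
        assert assign_gene(read, self.genes) is None
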