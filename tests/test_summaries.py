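"""Gene-level summaries, CPM, differential expression, histograms."""

import math

import numpy as np
import pandas as pd
import pytest

from tailscape.io_formats import GeneModel, TailRecord
from tailscape.pas_pdi import PasSite, ReadEndAssignment
from tailscape.summaries import (
    apa_isoform_tail_comparison,
    avg_u_length_per_tail,
    cpm,
    differential_expression,
    filter_gene_universe,
    gene_nona_proportion,
    gene_pdi_proportion,
    geometric_mean_tail_length,
    pdi_proportion,
    tail_length_histogram,
    transcript_nona_proportion,
)


def _rec(read_id, tail, gene="gA", pc=12):
    return TailRecord(
        barcode="bc", read_id=read_id, gene_id=gene, pass_count=pc,
        count_a=tail.count("A"), count_t=tail.count("T"),
        count_c=tail.count("C"), count_g=tail.count("G"),
        count_nona=tail.count("T") + tail.count("C") + tail.count("G"),
        tail_seq=tail,
    )


def _assign(read_id, category, gene="gA", end=100, pas=None):
    return ReadEndAssignment(read_id, gene, end, category, matched_pas=pas)


class TestGeometricMean:
    def test_constant(self):
        assert geometric_mean_tail_length([7, 7, 7]) == pytest.approx(7.0)

    def test_sqrt_of_product(self):
        assert geometric_mean_tail_length([10, 1000]) == pytest.approx(100.0)

    def test_permutation_invariant_and_bounded(self, rng):
        x = rng.integers(1, 300, size=50).tolist()
        a = geometric_mean_tail_length(x)
        b = geometric_mean_tail_length(sorted(x)[::-1])
        assert a == pytest.approx(b, rel=1e-12)
        assert min(x) <= a <= max(x)

    def test_matches_log_identity(self, rng):
        x = rng.integers(1, 500, size=200)
        expected = math.exp(float(np.mean(np.log(x))))
        assert geometric_mean_tail_length(x) == pytest.approx(expected, abs=1e-9)

    def test_empty_undefined(self):
        assert math.isnan(geometric_mean_tail_length([]))


class TestNonAProportions:
    records = [_rec("r1", "AATAA"), _rec("r2", "ATAAT"), _rec("r3", "AAAAA")]

    def test_transcript_fraction(self):
        assert transcript_nona_proportion(self.records, "T") == pytest.approx(2 / 3)

    def test_absent_base_zero(self):
        assert transcript_nona_proportion(self.records, "G") == 0.0

    def test_position_filter(self):
        # r2 ends in T (end3); r1 has only internal T
        assert transcript_nona_proportion(
            self.records, "T", position="end3"
        ) == pytest.approx(1 / 3)
        assert transcript_nona_proportion(
            self.records, "T", position="internal"
        ) == pytest.approx(1 / 3)
        # collapse mode counts both as internal
        assert transcript_nona_proportion(
            self.records, "T", position="internal", collapse_end3_to_internal=True
        ) == pytest.approx(2 / 3)

    def test_gene_level_min_reads(self):
        nineteen = [_rec(f"r{i}", "AT", gene="small") for i in range(19)]
        twenty = [_rec(f"s{i}", "AT", gene="big") for i in range(20)]
        out = gene_nona_proportion(nineteen + twenty, "T")
        assert list(out.index) == ["big"]
        assert out["big"] == 1.0


class TestPdiProportion:
    def test_formula_excludes_unassigned(self):
        assigns = (
            [_assign(f"p{i}", "PDI") for i in range(6)]
            + [_assign(f"i{i}", "PIT") for i in range(4)]
            + [_assign(f"u{i}", "UNASSIGNED") for i in range(2)]
        )
        assert pdi_proportion(assigns) == pytest.approx(0.6)

    def test_zero_pdi(self):
        assert pdi_proportion([_assign("a", "PIT")]) == 0.0

    def test_empty_denominator_undefined(self):
        assert pdi_proportion([_assign("a", "UNASSIGNED")]) is None

    def test_gene_level_min_reads(self):
        small = [_assign(f"a{i}", "PDI", gene="small") for i in range(10)]
        big = [_assign(f"b{i}", "PDI", gene="big") for i in range(10)] + [
            _assign(f"c{i}", "PIT", gene="big") for i in range(10)
        ]
        out = gene_pdi_proportion(small + big)
        assert list(out.index) == ["big"]
        assert out["big"] == pytest.approx(0.5)


class TestAvgULength:
    def test_mean_u_count(self):
        records = [_rec("r1", "ATTA"), _rec("r2", "AAAA"), _rec("r3", "ATAA")]
        assert avg_u_length_per_tail(records) == pytest.approx(1.0)

    def test_all_zero(self):
        assert avg_u_length_per_tail([_rec("r", "AAA")]) == 0.0

    def test_pdi_only_mode(self):
        records = [_rec("r1", "ATTTA"), _rec("r2", "AAAA")]
        assigns = [_assign("r1", "PDI"), _assign("r2", "PIT")]
        assert avg_u_length_per_tail(records, assigns, restrict="PDI") == 3.0


class TestApaComparison:
    sites = [PasSite(100, 40, "pPAS"), PasSite(200, 40, "dPAS")]

    def _data(self, n_p, n_d, len_p=20, len_d=40):
        records, assigns = [], []
        for i in range(n_p):
            records.append(_rec(f"p{i}", "A" * len_p))
            assigns.append(_assign(f"p{i}", "PIT", pas=100))
        for i in range(n_d):
            records.append(_rec(f"d{i}", "A" * len_d))
            assigns.append(_assign(f"d{i}", "PIT", pas=200))
        return records, assigns

    def test_reported_when_both_pass_threshold(self):
        records, assigns = self._data(25, 30)
        out = apa_isoform_tail_comparison(self.sites, assigns, records)
        assert out == (pytest.approx(20.0), pytest.approx(40.0))

    def test_excluded_when_one_side_short(self):
        records, assigns = self._data(25, 19)
        assert apa_isoform_tail_comparison(self.sites, assigns, records) is None

    def test_identical_tails_equal_means(self):
        records, assigns = self._data(25, 25, len_p=33, len_d=33)
        p, d = apa_isoform_tail_comparison(self.sites, assigns, records)
        assert p == pytest.approx(d)


class TestCpm:
    def test_formula_and_conservation(self):
        counts = pd.DataFrame(
            {"s1": [10, 999_990], "s2": [10, 990]}, index=["gA", "gB"]
        )
        out = cpm(counts)
        assert out.loc["gA", "s1"] == pytest.approx(10.0)
        assert out.loc["gA", "s2"] == pytest.approx(10_000.0)
        assert np.allclose(out.sum(axis=0), 1_000_000.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            cpm(pd.DataFrame({"s1": [0, 0]}, index=["gA", "gB"]))


class TestDifferentialExpression:
    def test_identical_groups_not_flagged(self):
        a = pd.DataFrame(np.full((5, 3), 50.0))
        out = differential_expression(a, a.copy())
        assert (out["log2fc"] == 0).all()
        assert (out["p"] == 1.0).all()
        assert (out["flag"] == "").all()

    def test_log2fc_with_pseudocount(self):
        a = pd.DataFrame([[10.0, 10.0, 10.0]])
        b = pd.DataFrame([[40.0, 40.5, 39.5]])
        out = differential_expression(a, b)
        assert out["log2fc"].iloc[0] == pytest.approx(math.log2(41 / 11), abs=1e-9)
        assert out["p"].iloc[0] < 0.05
        assert out["flag"].iloc[0] == "up"

    def test_one_tailed_direction(self):
        a = pd.DataFrame([[10.0, 11.0, 9.0, 10.0]])
        b = pd.DataFrame([[40.0, 41.0, 39.0, 40.0]])
        up = differential_expression(a, b, alternative="greater")["p"].iloc[0]
        down = differential_expression(a, b, alternative="less")["p"].iloc[0]
        assert up < 0.05 < down

    def test_requires_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            differential_expression(pd.DataFrame([[1.0]]), pd.DataFrame([[2.0]]))


class TestHistogram:
    def test_bimodal_median(self):
        lengths = [18] * 50 + [36] * 50
        density, median = tail_length_histogram(lengths)
        assert median == pytest.approx(27.0)
        assert density[18] == pytest.approx(0.5)
        assert density[36] == pytest.approx(0.5)

    def test_point_mass(self):
        density, median = tail_length_histogram([42])
        assert median == 42
        assert density[42] == 1.0

    def test_density_sums_to_one_with_overflow(self, rng):
        lengths = rng.integers(1, 500, size=300)
        density, _ = tail_length_histogram(lengths, max_len=250)
        assert density.sum() == pytest.approx(1.0)
        assert density[250] > 0  # pooled overflow


class TestGeneUniverse:
    def test_exclusion_list(self):
        records = [_rec("r1", "A", gene="HIST1"), _rec("r2", "A", gene="gB")]
        kept = filter_gene_universe(records, ["HIST1"])
        assert [r.gene_id for r in kept] == ["gB"]
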