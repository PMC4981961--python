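"""Read cleaning cascade, collapsing and length distributions."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miralga.qc import (QCReport, UniqueRead, clean_reads, collapse_unique,
                        length_distribution, redundancy_ratio, tabulate_report)
from miralga.synthio import ADAPTER_3P, ADAPTER_5P


def wrap(insert: str, qual: float = 40) -> tuple[str, str, str]:
    seq = ADAPTER_5P + insert + ADAPTER_3P
    return ("r", seq, chr(int(qual) + 33) * len(seq))


class TestLibraryAccounting:
    def test_published_library_arithmetic(self):
        """Clean reads follow from the printed high-quality and removal
        counts: 11,394,052 - removals = 10,911,139 = 95.76 %."""
        rep = tabulate_report(
            high_quality=11_394_052,
            removed={"adapter3_null": 754, "insert_null": 3_337,
                     "adapter5_contaminant": 179_642, "short_lt18": 298_272,
                     "polyA": 908},
            total_reads=11_425_306,
        )
        assert rep.clean_reads == 10_911_139
        assert rep.percentages["clean_reads"] == 95.76

    def test_empty_input_no_division_by_zero(self):
        unique, labels, rep = clean_reads([])
        assert rep.total_reads == 0 and rep.clean_reads == 0
        assert rep.percentages["clean_reads"] == 0.0
        assert unique == [] and labels == []

    def test_accounting_invariant_enforced(self):
        with pytest.raises(ValueError, match="accounting"):
            QCReport(total_reads=10, high_quality=10, clean_reads=9,
                     removed={"polyA": 2}).validate()


class TestFilterCascade:
    def _reads(self):
        rand = "UCGAUCGGACUAGCUAGAUCG"  # 21 nt clean insert
        return [
            ("lq1", ADAPTER_5P + rand + ADAPTER_3P, "#" * (len(ADAPTER_5P) + 21 + len(ADAPTER_3P))),
            ("lq2", ADAPTER_5P + rand + ADAPTER_3P, "#" * (len(ADAPTER_5P) + 21 + len(ADAPTER_3P))),
            ("a3_1", ADAPTER_5P + rand + "GGGGGGGGGG", "I" * (len(ADAPTER_5P) + 31)),
            ("a3_2", ADAPTER_5P + rand[::-1] + "GGGGGGGGGG", "I" * (len(ADAPTER_5P) + 31)),
            ("in1", ADAPTER_5P + ADAPTER_3P, "I" * (len(ADAPTER_5P) + len(ADAPTER_3P))),
            ("in2", ADAPTER_5P + ADAPTER_3P + "CCAA", "I" * (len(ADAPTER_5P) + len(ADAPTER_3P) + 4)),
            wrap("ACGU" + ADAPTER_5P + "GUCAUGCAUG"),
            wrap("CCGU" + ADAPTER_5P + "GUCAUGCAUG"),
            wrap("UCGAUCGGACU"),  # 11 nt -> short
            wrap("UCGAUCGGACUAG"),  # 13 nt -> short
            wrap("A" * 22),  # polyA
            wrap("A" * 19 + "C"),  # 95 % A -> polyA
            wrap(rand),
            wrap("GGCAUCGAUCGAUGGCAUAGC"),
        ]

    def test_labels_equal_manual_assignment(self):
        raw = self._reads()
        unique, labels, rep = clean_reads(raw)
        expected = ["low_quality"] * 2 + ["adapter3_null"] * 2 + \
            ["insert_null"] * 2 + ["adapter5_contaminant"] * 2 + \
            ["short_lt18"] * 2 + ["polyA"] * 2 + ["clean"] * 2
        assert labels == expected
        assert rep.high_quality == 12
        assert rep.clean_reads == 2
        assert all(rep.removed[c] == 2 for c in rep.removed)

    def test_every_read_lands_in_exactly_one_bucket(self):
        raw = self._reads()
        _, labels, rep = clean_reads(raw)
        n_low = labels.count("low_quality")
        assert rep.total_reads == len(raw)
        assert rep.high_quality == len(raw) - n_low
        assert rep.high_quality == rep.clean_reads + sum(rep.removed.values())

    def test_earlier_filter_wins_short_before_polya(self):
        # 12-nt all-A insert is both short and poly(A); short is counted
        _, labels, _ = clean_reads([wrap("A" * 12)])
        assert labels == ["short_lt18"]

    def test_cleaning_already_clean_inserts_is_idempotent(self):
        inserts = ["UCGAUCGGACUAGCUAGAUCG", "GGCAUCGAUCGAUGGCAUAGC"]
        unique, labels, rep = clean_reads([wrap(i) for i in inserts])
        assert sorted(u.sequence for u in unique) == sorted(inserts)
        assert rep.clean_reads == 2 and sum(rep.removed.values()) == 0

    def test_malformed_record_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            clean_reads([wrap("UCGAUCGGACUAGCUAGAUCG"), ("bad", "ACGU", "II")])


class TestCollapse:
    def test_published_redundancy_ratio(self):
        assert redundancy_ratio(10_911_139, 1_646_610) == 6.6

    def test_simple_collapse(self):
        out = collapse_unique(["AAA"] * 3 + ["CCC"] * 2)
        assert out == [UniqueRead("AAA", 3), UniqueRead("CCC", 2)]

    def test_all_distinct(self):
        reads = [f"ACGU{i:03d}".replace("0", "A").replace("1", "C")
                 .replace("2", "G").replace("3", "U").replace("4", "A")
                 .replace("5", "C").replace("6", "G").replace("7", "U")
                 .replace("8", "A").replace("9", "C") for i in range(50)]
        reads = list(dict.fromkeys(reads))
        out = collapse_unique(reads)
        assert len(out) == len(reads)
        assert redundancy_ratio(len(reads), len(out)) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGU", min_size=1, max_size=8), max_size=60))
    def test_counts_conserve_input_size(self, reads):
        out = collapse_unique(reads)
        assert sum(u.count for u in out) == len(reads)
        assert len({u.sequence for u in out}) == len(out)


class TestLengthDistribution:
    def test_two_length_mixture(self):
        unique = [UniqueRead("A" * 21, 401), UniqueRead("C" * 20, 599)]
        dist = length_distribution(unique, weighted=True)
        assert dist[21] == pytest.approx(401 / 1000, abs=1e-9)
        assert dist[20] == pytest.approx(599 / 1000, abs=1e-9)

    def test_single_read(self):
        assert length_distribution([UniqueRead("ACGU" * 5, 1)]) == {20: 1.0}

    def test_weighted_mode_reflects_planted_mass_at_21nt(self):
        # mixture built to put 40.14 % of read mass at 21 nt
        unique = [UniqueRead("A" * 21, 4014), UniqueRead("C" * 20, 3000),
                  UniqueRead("G" * 22, 2986)]
        dist = length_distribution(unique, weighted=True)
        assert max(dist, key=dist.get) == 21
        assert dist[21] == pytest.approx(0.4014, abs=1e-9)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            length_distribution([])
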