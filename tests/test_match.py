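"""Multi-pattern matching, hit aggregation and anomaly flagging."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spsr.fixtures import _encode
from spsr.match import (
    AhoCorasick,
    HitTable,
    build_matcher,
    flag_anomalies,
    scan_reads,
)
from spsr.sixframe import ShortRead, reverse_complement
from spsr.sp_dictionary import ECLabel, SPDictionary, SpecificPeptide


def naive_find(patterns, text):
    return {
        (i, j)
        for i, p in enumerate(patterns)
        for j in range(len(text) - len(p) + 1)
        if text[j : j + len(p)] == p
    }


def make_dict(pairs):
    return SPDictionary(frozenset(SpecificPeptide(s, ECLabel.parse(e)) for s, e in pairs))


class TestAhoCorasick:
    def test_tandem_repeat(self):
        ac = AhoCorasick(["ABCDEFG"])
        assert set(ac.find("ABCDEFGABCDEFG")) == {(0, 0), (0, 7)}

    def test_overlapping_occurrences_counted(self):
        ac = AhoCorasick(["AAAAAAA"])
        assert set(ac.find("AAAAAAAA")) == {(0, 0), (0, 1)}

    def test_empty_pattern_set_rejected(self):
        with pytest.raises(ValueError):
            AhoCorasick([])

    def test_nested_patterns_all_reported(self):
        ac = AhoCorasick(["ABC", "BC", "C"])
        hits = set(ac.find("ABC"))
        assert hits == {(0, 0), (1, 1), (2, 2)}

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.data())
    def test_equals_naive_oracle(self, data):
        # small alphabet forces overlaps, shared prefixes and tandem repeats
        alphabet = data.draw(st.sampled_from(["AB", "ABC", "ACGT"]))
        patterns = data.draw(
            st.lists(
                st.text(alphabet=alphabet, min_size=1, max_size=8),
                min_size=1, max_size=20, unique=True,
            )
        )
        text = data.draw(st.text(alphabet=alphabet, min_size=0, max_size=200))
        ac = AhoCorasick(patterns)
        assert set(ac.find(text)) == naive_find(patterns, text)


class TestScanReads:
    def test_single_planted_sp_counts_at_level3(self):
        d = make_dict([("NSISISGYH", "5.4.99.2")])
        rng = np.random.default_rng(0)
        read = ShortRead("r1", _encode("NSISISGYH", rng) + "ACGACG")
        _, table = scan_reads([read], build_matcher(d))
        assert table.counts == {"5.4.99": 1}

    def test_sp_split_across_reads_is_missed(self):
        d = make_dict([("NSISISGYH", "5.4.99.2")])
        rng = np.random.default_rng(0)
        enc = _encode("NSISISGYH", rng)
        half = len(enc) // 2
        reads = [ShortRead("a", "ACGTAC" + enc[:half]), ShortRead("b", enc[half:] + "ACGTAC")]
        _, table = scan_reads(reads, build_matcher(d))
        assert table.counts == {}

    def test_overlapping_sps_both_tallied(self):
        d = make_dict([("NSISISGYH", "5.4.99.2"), ("ISISGYHMQEAG", "5.4.99.2")])
        rng = np.random.default_rng(0)
        # one read encoding NSISISGYHMQEAG carries both overlapping SPs
        read = ShortRead("r", _encode("ANSISISGYHMQEAGA", rng))
        hits, table = scan_reads([read], build_matcher(d))
        assert table.counts == {"5.4.99": 2}
        assert {h.sp_sequence for h in hits} == {"NSISISGYH", "ISISGYHMQEAG"}

    def test_strand_symmetry(self, small_fixture):
        from spsr.calibrate import simulate_reads

        matcher = build_matcher(small_fixture.dictionary)
        reads = simulate_reads(small_fixture.genomes[0].sequence, 60, 2.0, seed=3)
        _, fwd = scan_reads(reads, matcher)
        rc = [ShortRead(r.id, reverse_complement(r.sequence)) for r in reads]
        _, rev = scan_reads(rc, matcher)
        assert fwd.counts == rev.counts

    def test_shift_invariance(self):
        d = make_dict([("NSISISGYH", "5.4.99.2")])
        rng = np.random.default_rng(1)
        enc = _encode("NSISISGYH", rng)
        base = ShortRead("r", enc + "ACGT")
        shifted = ShortRead("r", "ACG" * 4 + enc + "ACGT")
        hits0, t0 = scan_reads([base], build_matcher(d))
        hits1, t1 = scan_reads([shifted], build_matcher(d))
        assert t0.counts == t1.counts
        (h0,), (h1,) = hits0, hits1
        assert h1.frame == h0.frame == 0
        assert h1.offset_aa == h0.offset_aa + 4

    def test_taxon_keyed_aggregation(self, taxon_fixture):
        matcher = build_matcher(taxon_fixture.dictionary)
        g = taxon_fixture.genomes[0]
        _, table = scan_reads([ShortRead(g.genome_id, g.sequence)], matcher, key="taxon")
        assert set(table.counts) == {"Proteobacteria"}


class TestFlagAnomalies:
    def test_dominated_narrow_category_flagged(self):
        table = HitTable(
            counts={"5.4.99": 461, "1.1.1": 40, "2.7.7": 31},
            sp_counts={
                "5.4.99": Counter({"NSISISGYH": 276, "ISISGYHMQEAG": 185}),
                "1.1.1": Counter({f"SP{i}": 8 for i in range(5)}),
                "2.7.7": Counter({f"SQ{i}": 10 for i in range(3)}),
            },
        )
        reports = flag_anomalies(table)
        assert len(reports) == 1
        assert reports[0].category == "5.4.99"
        assert reports[0].supporting_sps == ("ISISGYHMQEAG", "NSISISGYH")

    def test_broadly_supported_dominance_not_flagged(self):
        table = HitTable(
            counts={"5.4.99": 461, "1.1.1": 40},
            sp_counts={
                "5.4.99": Counter({f"SP{i}": 40 for i in range(12)}),
                "1.1.1": Counter({"A" * 7: 40}),
            },
        )
        assert flag_anomalies(table) == []

    def test_uniform_counts_not_flagged(self):
        table = HitTable(
            counts={f"1.1.{i}": 30 for i in range(1, 11)},
            sp_counts={f"1.1.{i}": Counter({"A" * 7: 30}) for i in range(1, 11)},
        )
        assert flag_anomalies(table) == []

    def test_single_category_has_no_comparator(self):
        table = HitTable(counts={"5.4.99": 1000}, sp_counts={"5.4.99": Counter({"A" * 7: 1000})})
        assert flag_anomalies(table) == []
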