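"""Suffix array, LCP, supporting reads and maximal extensions vs brute force."""

import random

import pytest

from grasp.seqio import ReadSet, SequenceError
from grasp.suffix_index import (
    SupportingRead,
    build_index,
    find_supporting_reads,
    maximal_extensions,
    range_query,
)

from _oracles import (
    brute_maximal,
    brute_pattern_positions,
    brute_supporting,
    naive_lcp,
    naive_suffix_array,
)
from conftest import random_protein, random_readset


class TestBuild:
    def test_sa_and_lcp_match_naive(self, rng):
        for _ in range(20):
            rs = random_readset(rng, rng.randint(1, 8), 12)
            idx = build_index(rs)
            assert list(idx.sa) == naive_suffix_array(idx.text)
            assert list(idx.lcp) == naive_lcp(idx.text, list(idx.sa))

    def test_single_one_residue_read(self):
        idx = build_index(ReadSet([("r", "A")]))
        i, j = idx.range_query("A")
        assert j - i == 1
        assert idx.locate(int(idx.sa[i])) == (0, 0)

    def test_delimiter_in_read_rejected(self):
        with pytest.raises(SequenceError):
            build_index(ReadSet([("r", "A#B")]))

    def test_build_deterministic(self, rng):
        rs = random_readset(rng, 10, 20)
        a, b = build_index(rs), build_index(rs)
        assert list(a.sa) == list(b.sa) and list(a.lcp) == list(b.lcp)

    def test_locate_resolves_every_residue_position(self, rng):
        rs = random_readset(rng, 5, 10)
        idx = build_index(rs)
        for pos in range(len(idx.text)):
            if idx.text[pos] == "#":
                continue
            rid, off = idx.locate(pos)
            assert rs.seqs[rid][off] == idx.text[pos]


class TestRangeQuery:
    def test_known_counts(self):
        idx = build_index(ReadSet([("a", "ACDG"), ("b", "CDGH")]))
        i, j = range_query(idx, "CDG")
        assert j - i == 2
        assert range_query(idx, "Z")[0] == range_query(idx, "Z")[1]
        long = "ACDGHACDGH"
        i, j = range_query(idx, long)
        assert i == j  # longer than every read

    def test_matches_brute_force_scan(self, rng):
        for _ in range(30):
            rs = random_readset(rng, rng.randint(1, 12), 15)
            idx = build_index(rs)
            for _ in range(10):
                plen = rng.randint(1, 4)
                if rng.random() < 0.5:
                    seq = rs.seqs[rng.randrange(len(rs))]
                    start = rng.randint(0, max(0, len(seq) - plen))
                    pattern = seq[start : start + plen]
                else:
                    pattern = random_protein(rng, plen)
                if not pattern:
                    continue
                i, j = range_query(idx, pattern)
                got = sorted(idx.locate(int(idx.sa[t])) for t in range(i, j))
                assert got == brute_pattern_positions(rs.seqs, pattern)


class TestSupportingReads:
    def test_worked_example(self):
        rs = ReadSet([("LAGG", "LAGG"), ("VLAG", "VLAG"), ("AAAA", "AAAA")])
        fwd, rev = build_index(rs), build_index(rs, True)
        got = {
            (rs.ids[s.read_id], s.overlap_len)
            for s in find_supporting_reads(fwd, rev, "MKVLA", 2, "right")
        }
        assert got == {("LAGG", 2), ("VLAG", 3)}

    def test_no_support_when_no_overlap(self):
        rs = ReadSet([("AAAA", "AAAA")])
        fwd, rev = build_index(rs), build_index(rs, True)
        assert find_supporting_reads(fwd, rev, "MKVLA", 2, "right") == []

    def test_read_equal_to_path_suffix_excluded(self):
        # full containment leaves an empty extension: cannot extend
        rs = ReadSet([("r", "VLA")])
        fwd, rev = build_index(rs), build_index(rs, True)
        assert find_supporting_reads(fwd, rev, "MKVLA", 2, "right") == []

    def test_path_shorter_than_l_errors(self):
        rs = ReadSet([("r", "VLA")])
        fwd, rev = build_index(rs), build_index(rs, True)
        with pytest.raises(ValueError):
            find_supporting_reads(fwd, rev, "MK", 3, "right")

    @pytest.mark.parametrize("direction", ["right", "left"])
    def test_matches_brute_force(self, rng, direction):
        for _ in range(100):
            rs = random_readset(rng, rng.randint(1, 10), 12)
            fwd, rev = build_index(rs), build_index(rs, True)
            l = rng.randint(1, 4)
            if rng.random() < 0.6:  # bias toward paths sharing read content
                seq = rs.seqs[rng.randrange(len(rs))]
                p = random_protein(rng, rng.randint(0, 4)) + seq[: rng.randint(1, len(seq))]
            else:
                p = random_protein(rng, rng.randint(1, 15))
            if len(p) < l:
                continue
            got = {
                (s.read_id, s.overlap_len, s.extension)
                for s in find_supporting_reads(fwd, rev, p, l, direction)
            }
            assert got == brute_supporting(rs.seqs, p, l, direction)


class TestMaximalExtensions:
    def _candidates(self, reads, p, l):
        rs = ReadSet((f"r{i}", s) for i, s in enumerate(reads))
        fwd, rev = build_index(rs), build_index(rs, True)
        sup = find_supporting_reads(fwd, rev, p, l, "right")
        return sup, maximal_extensions(fwd, p, l, sup)

    def test_prefix_subsumption_merges_weight(self):
        _, cands = self._candidates(["LAGG", "VLAG"], "MKVLA", 2)
        assert [(c.extension, c.weight) for c in cands] == [("GG", 2)]

    def test_incomparable_extensions_both_kept(self):
        _, cands = self._candidates(["LAAA", "LACC"], "MKVLA", 2)
        assert {(c.extension, c.weight) for c in cands} == {("AA", 1), ("CC", 1)}

    def test_single_supporting_read(self):
        _, cands = self._candidates(["LAG"], "MKVLA", 2)
        assert [(c.extension, c.weight) for c in cands] == [("G", 1)]

    def test_matches_brute_force_maximality(self, rng):
        for _ in range(100):
            rs = random_readset(rng, rng.randint(1, 10), 12)
            fwd, rev = build_index(rs), build_index(rs, True)
            l = rng.randint(1, 3)
            seq = rs.seqs[rng.randrange(len(rs))]
            p = random_protein(rng, rng.randint(0, 3)) + seq[: rng.randint(1, len(seq))]
            if len(p) < l:
                continue
            sup = find_supporting_reads(fwd, rev, p, l, "right")
            cands = maximal_extensions(fwd, p, l, sup)
            got = {c.extension for c in cands}
            assert got == brute_maximal({s.extension for s in sup})
            # weights: supporting reads whose extension prefixes the maximal one
            for c in cands:
                expect = [
                    s.read_id for s in sup if c.extension.startswith(s.extension)
                ]
                assert sorted(c.supporting_read_ids) == sorted(expect)

    def test_empty_supporting_gives_empty(self, rng):
        rs = random_readset(rng, 3, 8)
        fwd = build_index(rs)
        assert maximal_extensions(fwd, "MKVLAGWD", 3, []) == []
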