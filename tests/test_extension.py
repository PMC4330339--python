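"""The guided extension engine: tiling recovery, priority, termination."""

import random
from types import SimpleNamespace

import pytest

from grasp.extension import (
    ExtensionQueue,
    RedundancyTable,
    check_termination,
    extend_direction,
    init_extension,
)
from grasp.scoring import ScoringScheme
from grasp.seeding import SeedPair
from grasp.seqio import ProteinSequence, ReadSet
from grasp.suffix_index import build_index

from conftest import random_protein


def tiling_fixture(seed=3, length=40, read_len=12, stride=4):
    """Reads exactly tiling one source; query equals the source."""
    rng = random.Random(seed)
    src = random_protein(rng, length)
    reads = ReadSet(
        (f"t{s}", src[s : s + read_len])
        for s in range(0, length - read_len + 1, stride)
    )
    return src, reads


@pytest.fixture(scope="module")
def tiling():
    src, reads = tiling_fixture()
    scheme = ScoringScheme(k=4, seed_score_min=8, l=5, d=8, dropoff=30)
    query = ProteinSequence("q", src)
    fwd, rev = build_index(reads), build_index(reads, True)
    # seed on the k-mer at source position 16, from the read starting there
    rid = reads.index_of["t16"]
    kmer = src[16:20]
    seed = SeedPair(16, rid, 0, 4, 20, kmer, kmer)
    return SimpleNamespace(
        src=src, reads=reads, scheme=scheme, query=query, fwd=fwd, rev=rev, seed=seed
    )


class TestExtendDirection:
    def test_right_extension_recovers_tail(self, tiling):
        # the query window runs h residues ahead of the path, so right
        # extension terminates (query exhausted) with the path at 36 and
        # the window at the sequence end (40); reads wholly inside the
        # assembled stretch are the constituents
        paths = extend_direction(
            tiling.seed, "right", tiling.query, tiling.reads,
            tiling.fwd, tiling.rev, tiling.scheme,
        )
        assert len(paths) == 1
        assert paths[0].seq == tiling.src[16:36]
        assert paths[0].q_start == 16 and paths[0].q_end == len(tiling.src)
        got = {tiling.reads.ids[rid] for rid, _ in paths[0].constituents}
        assert got == {"t16", "t20", "t24"}

    def test_left_extension_recovers_head(self, tiling):
        paths = extend_direction(
            tiling.seed, "left", tiling.query, tiling.reads,
            tiling.fwd, tiling.rev, tiling.scheme,
        )
        assert len(paths) == 1
        assert paths[0].seq == tiling.src[4:20]
        assert paths[0].q_start == 0 and paths[0].q_end == 20
        got = {tiling.reads.ids[rid] for rid, _ in paths[0].constituents}
        assert got == {"t4", "t8"}

    def test_constituent_containment(self, tiling):
        for direction in ("right", "left"):
            for p in extend_direction(
                tiling.seed, direction, tiling.query, tiling.reads,
                tiling.fwd, tiling.rev, tiling.scheme,
            ):
                for rid, off in p.constituents:
                    rseq = tiling.reads.seqs[rid]
                    assert p.seq[off : off + len(rseq)] == rseq

    def test_decoy_reads_never_used(self, tiling):
        # decoys share < l residues with any path built from the source
        rng = random.Random(99)
        decoys = [(f"d{i}", random_protein(rng, 12)) for i in range(5)]
        reads = ReadSet(list(zip(tiling.reads.ids, tiling.reads.seqs)) + decoys)
        fwd, rev = build_index(reads), build_index(reads, True)
        for direction in ("right", "left"):
            for p in extend_direction(
                tiling.seed, direction, tiling.query, reads, fwd, rev, tiling.scheme
            ):
                names = {reads.ids[rid] for rid, _ in p.constituents}
                assert not any(n.startswith("d") for n in names)

    def test_deterministic_output(self, tiling):
        runs = [
            extend_direction(
                tiling.seed, "right", tiling.query, tiling.reads,
                tiling.fwd, tiling.rev, tiling.scheme,
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_seed_at_query_end_stops_immediately(self, tiling):
        src, reads = tiling.src, tiling.reads
        rid = reads.index_of["t28"]
        kmer = src[36:40]
        seed = SeedPair(36, rid, 8, 4, 20, kmer, kmer)
        paths = extend_direction(
            seed, "right", tiling.query, reads, tiling.fwd, tiling.rev, tiling.scheme
        )
        assert len(paths) == 1 and paths[0].seq == kmer  # query exhausted


class TestInitExtension:
    def test_no_supporting_reads_gives_empty_queue(self, tiling):
        # a seed whose k-mer content appears nowhere else: use decoy-only db
        rng = random.Random(5)
        reads = ReadSet([("only", random_protein(rng, 12))])
        fwd, rev = build_index(reads), build_index(reads, True)
        kmer = reads.seqs[0][:4]
        seed = SeedPair(0, 0, 0, 4, 20, kmer, kmer)
        query = ProteinSequence("q", kmer + random_protein(rng, 20))
        AS, pq = init_extension(seed, "right", query, reads, fwd, rev, tiling.scheme)
        assert len(AS) == 1 and AS[0].seq == kmer
        # the only read starts with the k-mer itself, so it can extend;
        # re-run with a seed k-mer taken mid-read: no read prefix matches
        kmer2 = reads.seqs[0][4:8]
        seed2 = SeedPair(0, 0, 4, 4, 20, kmer2, kmer2)
        query2 = ProteinSequence("q2", kmer2 + random_protein(rng, 20))
        AS2, pq2 = init_extension(seed2, "right", query2, reads, fwd, rev, tiling.scheme)
        assert len(pq2) == 0

    def test_supported_seed_fills_queue(self, tiling):
        AS, pq = init_extension(
            tiling.seed, "right", tiling.query, tiling.reads,
            tiling.fwd, tiling.rev, tiling.scheme,
        )
        assert len(pq) == 1  # identical tiling reads collapse to one candidate


class TestQueueAndTermination:
    def _cand(self, weight, ext, score, qkeys):
        return SimpleNamespace(
            weight=weight, extension=ext, state=SimpleNamespace(score=score), qkeys=qkeys
        )

    def test_heaviest_candidate_pops_first(self):
        pq = ExtensionQueue()
        pq.push(self._cand(1, "A", 0, []))
        pq.push(self._cand(3, "C", 0, []))
        pq.push(self._cand(2, "B", 0, []))
        assert [pq.pop().weight for _ in range(3)] == [3, 2, 1]

    def test_weight_tie_breaks_on_longer_extension(self):
        pq = ExtensionQueue()
        pq.push(self._cand(2, "A", 0, []))
        pq.push(self._cand(2, "AGG", 0, []))
        assert pq.pop().extension == "AGG"

    def test_score_dropoff(self, scheme):
        path = SimpleNamespace(best_score=100)
        keep = self._cand(1, "A", 71, [(0, 5)])
        drop = self._cand(1, "C", 69, [(1, 6)])
        out = check_termination(path, [keep, drop], scheme, RedundancyTable(), False)
        assert out == [keep]

    def test_redundant_extension_dropped(self, scheme):
        path = SimpleNamespace(best_score=0)
        red = RedundancyTable()
        first = self._cand(1, "A", 0, [(0, 5), (1, 7)])
        assert check_termination(path, [first], scheme, red, False) == [first]
        again = self._cand(1, "A", 0, [(0, 5), (1, 7)])
        assert check_termination(path, [again], scheme, red, False) == []
        partial = self._cand(1, "A", 0, [(0, 5), (2, 9)])  # one new read
        assert check_termination(path, [partial], scheme, red, False) == [partial]

    def test_query_exhaustion_drops_everything(self, scheme):
        path = SimpleNamespace(best_score=0)
        cand = self._cand(1, "A", 0, [(0, 5)])
        assert check_termination(path, [cand], scheme, RedundancyTable(), True) == []
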