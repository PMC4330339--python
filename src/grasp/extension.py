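"""Guided path extension: the core of the simultaneous search-and-assembly.

Starting from a seed k-mer pair, paths are grown one maximal extension
sequence at a time, first toward the query C-terminus ("right"), then —
restarting from the same seed — toward the N-terminus ("left").  A
priority queue orders candidate extensions by weight (the number of
supporting reads the extension subsumes), so well-covered continuations
are explored first.  Each accepted extension drags the banded alignment
along incrementally via the stored boundary scores.

Extension of a path stops on one of three conditions: sequence exhaustion
(the alignment reached an end of the query, or no read overlaps the path
tip by >= l), score drop-off (the extended score falls more than
``dropoff`` below the best score on the path's chain, as in BLAST), and
redundant extension (every supporting read of the candidate was already
consumed at the same query position by an earlier extension of this
seed's search).

Left extension is implemented by running the right-extension machinery in
mirror space: the query, the path and the read set are all reversed, so
the forward and reverse suffix indexes simply swap roles.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from .banded import BandBoundary, banded_extend, initial_boundary
from .scoring import ScoringScheme
from .seeding import SeedPair
from .seqio import ProteinSequence, ReadSet
from .suffix_index import (
    SuffixIndex,
    SupportingRead,
    find_supporting_reads,
    maximal_extensions,
)


@dataclass(frozen=True)
class AssemblyPath:
    """A finished (reported) assembly path in global orientation.

    ``q_start``/``q_end`` are 0-based half-open coordinates on the query;
    constituents are (read index, offset of the read within ``seq``).
    Every constituent read is an exact substring of ``seq`` at its offset.
    """

    seq: str
    q_start: int
    q_end: int
    constituents: tuple[tuple[int, int], ...]
    score: int
    direction: str
    seed: SeedPair


@dataclass
class RedundancyTable:
    """(read, query-position) pairs already consumed within one seed search."""

    seen: set[tuple[int, int]] = field(default_factory=set)


class ExtensionQueue:
    """Max-weight priority queue of extension candidates.

    Ties break on longer extension first, then lexicographic extension,
    then insertion order — a total order, so runs are deterministic.
    """

    def __init__(self) -> None:
        self._heap: list = []
        self._n = 0

    def push(self, cand: "_Candidate") -> None:
        key = (-cand.weight, -len(cand.extension), cand.extension, self._n)
        heapq.heappush(self._heap, (key, cand))
        self._n += 1

    def pop(self) -> "_Candidate":
        return heapq.heappop(self._heap)[1]

    def __len__(self) -> int:
        return len(self._heap)


@dataclass
class _Candidate:
    """A scored, admissible extension of ``parent`` (local orientation)."""

    extension: str
    weight: int
    supports: list[tuple[int, int]]  # (read_id, overlap)
    state: BandBoundary
    parent: "_Node"
    qkeys: list[tuple[int, int]]  # redundancy keys of the supports


class _Node:
    """A path in the growing AS tree, in local (rightward) orientation."""

    __slots__ = (
        "seq", "state", "score", "best_score", "best_node",
        "constituents", "parent",
    )

    def __init__(self, seq, state, score, parent, constituents):
        self.seq = seq
        self.state = state
        self.score = score
        self.parent = parent
        self.constituents = constituents
        if parent is None or score >= parent.best_score:
            self.best_score = score
            self.best_node = self
        else:
            self.best_score = parent.best_score
            self.best_node = parent.best_node


def check_termination(
    path: "_Node",
    candidates: list[_Candidate],
    scheme: ScoringScheme,
    redundancy: RedundancyTable,
    q_exhausted: bool,
) -> list[_Candidate]:
    """Apply the three termination criteria; register survivors' reads."""
    if q_exhausted:
        return []
    out = []
    for cand in candidates:
        if cand.state.score < path.best_score - scheme.dropoff:
            continue  # score drop-off
        if all(key in redundancy.seen for key in cand.qkeys):
            continue  # redundant extension
        redundancy.seen.update(cand.qkeys)
        out.append(cand)
    return out


class _Engine:
    """Right-extension engine over one orientation of the problem."""

    def __init__(self, seed, direction, query, reads, fwd, rev_idx, scheme, redundancy, log=None):
        self.seed = seed
        self.direction = direction
        self.scheme = scheme
        self.redundancy = redundancy
        self.reads = reads
        self.log = log
        self.Qlen = len(query)
        if direction == "right":
            self.Qv = query.residues
            self.a0 = seed.q_pos
            self.local_fwd, self.local_rev = fwd, rev_idx
            st_local = seed.r_kmer
            sq_local = seed.q_kmer
        else:
            self.Qv = query.residues[::-1]
            self.a0 = len(query) - seed.q_pos - seed.k
            self.local_fwd, self.local_rev = rev_idx, fwd
            st_local = seed.r_kmer[::-1]
            sq_local = seed.q_kmer[::-1]
        state = banded_extend(initial_boundary(scheme.half_band), st_local, sq_local, scheme)
        if state is None:  # k > h would be required for this; guard anyway
            raise ValueError("seed k-mer does not fit the alignment band")
        self.root = _Node(st_local, state, state.score, None, ())

    # -- local <-> global mapping -----------------------------------------

    def _qkey(self, node_len: int, read_id: int, overlap: int) -> tuple[int, int]:
        """Redundancy key: (read, nominal global q position of read start)."""
        t = node_len - overlap  # local path offset of the read start
        n = len(self.reads.seqs[read_id])
        if self.direction == "right":
            return read_id, self.a0 + t
        return read_id, self.Qlen - self.a0 - t - n

    def _candidates(self, node: _Node) -> list[_Candidate]:
        scheme = self.scheme
        l_eff = min(scheme.l, len(node.seq))
        if self.direction == "right":
            sup = find_supporting_reads(
                self.local_fwd, self.local_rev, node.seq, l_eff, "right"
            )
        else:
            # mirror space: the global-orientation call returns prefixes to
            # prepend; flip them into local (append) orientation
            sup_g = find_supporting_reads(
                self.local_rev, self.local_fwd, node.seq[::-1], l_eff, "left"
            )
            sup = [
                SupportingRead(s.read_id, s.overlap_len, s.extension[::-1])
                for s in sup_g
            ]
        if not sup:
            return []
        cands = maximal_extensions(self.local_fwd, node.seq, l_eff, sup)
        rem = len(self.Qv) - self.a0  # query residues available locally
        out = []
        for c in cands:
            q_target = min(node.state.I + len(c.extension) + scheme.half_band, rem)
            q_ext = self.Qv[
                self.a0 + node.state.J : self.a0 + max(node.state.J, q_target)
            ]
            new_state = banded_extend(node.state, c.extension, q_ext, scheme)
            if new_state is None:
                continue  # band cannot connect the extension
            supports = list(zip(c.supporting_read_ids, c.overlaps))
            qkeys = [
                self._qkey(len(node.seq) + len(c.extension), rid, o)
                for rid, o in supports
            ]
            out.append(_Candidate(c.extension, c.weight, supports, new_state, node, qkeys))
        return out

    def _admissible(self, node: _Node) -> list[_Candidate]:
        q_exhausted = self.a0 + node.state.J >= len(self.Qv)
        cands = [] if q_exhausted else self._candidates(node)
        return check_termination(node, cands, self.scheme, self.redundancy, q_exhausted)

    def run(self) -> list[AssemblyPath]:
        pq = ExtensionQueue()
        leaves: list[_Node] = []
        first = self._admissible(self.root)
        if not first:
            leaves.append(self.root)
        for cand in first:
            pq.push(cand)
        while len(pq):
            cand = pq.pop()
            parent = cand.parent
            child_seq = parent.seq + cand.extension
            new_constituents = tuple(
                (rid, len(parent.seq) - o) for rid, o in cand.supports
            )
            child = _Node(
                child_seq,
                cand.state,
                cand.state.score,
                parent,
                parent.constituents + new_constituents,
            )
            if self.log is not None:
                self.log(
                    f"seed q{self.seed.q_pos} r{self.seed.read_id}:{self.seed.r_pos} "
                    f"{self.direction} len={len(child_seq)} w={cand.weight} "
                    f"score={child.score}"
                )
            nxt = self._admissible(child)
            if not nxt:
                leaves.append(child)
            for c in nxt:
                pq.push(c)
        # report the best-scoring state on each root-to-leaf chain
        best_nodes: list[_Node] = []
        seen_ids: set[int] = set()
        for leaf in leaves:
            node = leaf.best_node
            if id(node) not in seen_ids:
                seen_ids.add(id(node))
                best_nodes.append(node)
        paths = [self._to_global(n) for n in best_nodes]
        return _maximal_paths(paths)

    def _to_global(self, node: _Node) -> AssemblyPath:
        if self.direction == "right":
            q_start = self.a0
            q_end = self.a0 + node.state.J
            seq = node.seq
            constituents = tuple(sorted(node.constituents))
        else:
            q_end = self.Qlen - self.a0
            q_start = self.Qlen - self.a0 - node.state.J
            seq = node.seq[::-1]
            constituents = tuple(
                sorted(
                    (rid, len(seq) - off - len(self.reads.seqs[rid]))
                    for rid, off in node.constituents
                )
            )
        return AssemblyPath(
            seq, q_start, q_end, constituents, node.score, self.direction, self.seed
        )


def _maximal_paths(paths: list[AssemblyPath]) -> list[AssemblyPath]:
    """Drop paths whose sequence is a substring of another reported path."""
    paths = sorted(
        paths, key=lambda p: (-len(p.seq), p.seq, -len(p.constituents), -p.score)
    )
    kept: list[AssemblyPath] = []
    for p in paths:
        dominated = False
        for q in kept:
            if p.seq in q.seq:
                dominated = True
                break
        if not dominated:
            kept.append(p)
    return kept


def init_extension(
    seed: SeedPair,
    direction: str,
    query: ProteinSequence,
    reads: ReadSet,
    fwd: SuffixIndex,
    rev_idx: SuffixIndex,
    scheme: ScoringScheme,
    redundancy: RedundancyTable | None = None,
):
    """Initial path set and queue for one seed and direction (AS, PQ)."""
    redundancy = redundancy if redundancy is not None else RedundancyTable()
    eng = _Engine(seed, direction, query, reads, fwd, rev_idx, scheme, redundancy)
    pq = ExtensionQueue()
    for cand in eng._admissible(eng.root):
        pq.push(cand)
    return [eng.root], pq


def extend_direction(
    seed: SeedPair,
    direction: str,
    query: ProteinSequence,
    reads: ReadSet,
    fwd: SuffixIndex,
    rev_idx: SuffixIndex,
    scheme: ScoringScheme,
    redundancy: RedundancyTable | None = None,
    log=None,
) -> list[AssemblyPath]:
    """All maximal assembly paths for one seed in one direction."""
    if direction not in ("right", "left"):
        raise ValueError(f"direction must be 'right' or 'left', got {direction!r}")
    redundancy = redundancy if redundancy is not None else RedundancyTable()
    eng = _Engine(seed, direction, query, reads, fwd, rev_idx, scheme, redundancy, log=log)
    return eng.run()
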