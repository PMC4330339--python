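"""Merging of left/right paths, E-values and output contigs.

For each seed, the left and right extension phases each produce a set of
paths that share the seed k-mer (as suffix and prefix respectively).  A
left/right pair may be concatenated when enough *bridging reads* license
the junction: a bridging read contains the seed k-mer with its upstream
part matching the left path and its downstream part matching the right
path.  Pairs supported by the same bridging-read set are rank-paired by
score; the merged score is the sum of both path scores minus the ungapped
seed score (counted once per side otherwise).  Paths that cannot be
merged are reported individually.

E-values follow the Karlin-Altschul form E = K * m * n * exp(-lambda * S)
with m the query length and n the database residue count.  The final
contig set is substring-free: no reported contig is a substring of
another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .extension import AssemblyPath
from .scoring import ScoringScheme
from .seeding import SeedPair
from .seqio import ReadSet
from .suffix_index import SuffixIndex


@dataclass
class Contig:
    """A merged, scored, E-valued output sequence with read provenance."""

    id: str
    seq: str
    query_id: str
    q_start: int  # 0-based half-open internally
    q_end: int
    score: int
    evalue: float
    constituents: tuple[tuple[int, int], ...]  # (read index, offset in seq)
    seed: SeedPair | None = None

    @property
    def n_reads(self) -> int:
        return len({rid for rid, _ in self.constituents})


@dataclass
class SearchResult:
    contigs: list[Contig]
    unassigned_reads: list[int]
    scheme: ScoringScheme
    query_id: str
    recruited: list[tuple[int, int, int]] = field(default_factory=list)
    # (read index, contig position in `contigs`, offset) appended by recruit_reads


def evalue(score: int, query_len: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expectation of a score this high arising by chance."""
    if query_len <= 0 or scheme.m_db <= 0:
        raise ValueError("query and database lengths must be positive")
    return scheme.K_ * query_len * scheme.m_db * math.exp(-scheme.lambda_ * score)


def find_bridging_reads(
    seed: SeedPair,
    left: AssemblyPath,
    right: AssemblyPath,
    idx: SuffixIndex,
) -> list[int]:
    """Reads containing s^T whose flanks match the left and right paths.

    For an occurrence of the seed k-mer at read offset t, the read bridges
    when read[:t+k] is a suffix of the left path and read[t:] is a prefix
    of the right path.
    """
    i, j = idx.range_query(seed.r_kmer)
    reads = idx.reads
    k = seed.k
    hits: set[int] = set()
    for s in range(i, j):
        rid, t = idx.locate(int(idx.sa[s]))
        seq = reads.seqs[rid]
        if len(seq) - t < k:  # k-mer spills over the read end (cannot happen
            continue  # with residue-only patterns, kept for clarity)
        if left.seq.endswith(seq[: t + k]) and right.seq.startswith(seq[t:]):
            hits.add(rid)
    return sorted(hits)


def merge_paths(
    lefts: list[AssemblyPath],
    rights: list[AssemblyPath],
    seed: SeedPair,
    scheme: ScoringScheme,
    idx: SuffixIndex,
    reads: ReadSet,
    query_id: str,
    query_len: int,
) -> list[Contig]:
    """Concatenate rank-paired left/right paths; pass the rest through."""
    k = seed.k
    bridge_groups: dict[tuple[int, ...], tuple[set[int], set[int]]] = {}
    bridges: dict[tuple[int, int], list[int]] = {}
    for li, L in enumerate(lefts):
        for ri, R in enumerate(rights):
            B = find_bridging_reads(seed, L, R, idx)
            if len(B) >= scheme.min_bridge:
                key = tuple(B)
                grp = bridge_groups.setdefault(key, (set(), set()))
                grp[0].add(li)
                grp[1].add(ri)
                bridges[(li, ri)] = B

    def rank_key(path: AssemblyPath):
        return (-path.score, -len(path.seq), path.seq)

    contigs: list[Contig] = []
    used_l: set[int] = set()
    used_r: set[int] = set()
    serial = 0

    def _contig(seq, q_start, q_end, score, constituents) -> Contig:
        nonlocal serial
        cid = f"{query_id}|s{seed.q_pos}.{seed.read_id}.{seed.r_pos}|c{serial}"
        serial += 1
        return Contig(
            cid, seq, query_id, q_start, q_end, score,
            evalue(score, query_len, scheme), tuple(sorted(set(constituents))), seed,
        )

    for key in sorted(bridge_groups):
        lset, rset = bridge_groups[key]
        ls = sorted((lefts[i] for i in lset), key=rank_key)
        rs = sorted((rights[i] for i in rset), key=rank_key)
        for L, R in zip(ls, rs):
            li = lefts.index(L)
            ri = rights.index(R)
            if (li, ri) not in bridges:
                continue  # same-rank pair not actually bridged by this set
            seq = L.seq + R.seq[k:]
            score = L.score + R.score - seed.seed_score
            constituents = list(L.constituents)
            constituents += [
                (rid, off + len(L.seq) - k) for rid, off in R.constituents
            ]
            for rid in bridges[(li, ri)]:
                rseq = reads.seqs[rid]
                t = rseq.find(seed.r_kmer)
                while t != -1:
                    off = len(L.seq) - (t + k)
                    if 0 <= off <= len(seq) - len(rseq) and seq[off : off + len(rseq)] == rseq:
                        constituents.append((rid, off))
                        break
                    t = rseq.find(seed.r_kmer, t + 1)
            contigs.append(
                _contig(seq, L.q_start, R.q_end, score, constituents)
            )
            used_l.add(li)
            used_r.add(ri)
    for li, L in enumerate(lefts):
        if li not in used_l:
            contigs.append(_contig(L.seq, L.q_start, L.q_end, L.score, L.constituents))
    for ri, R in enumerate(rights):
        if ri not in used_r:
            contigs.append(_contig(R.seq, R.q_start, R.q_end, R.score, R.constituents))
    return contigs


def dedupe_contigs(
    contigs: list[Contig], scheme: ScoringScheme, reads: ReadSet, query_id: str
) -> SearchResult:
    """Substring-free, E-value-filtered final contig set.

    On exact sequence ties the contig with more constituent reads wins,
    then lower E-value, then lexicographically smallest id.
    """
    order = sorted(
        contigs,
        key=lambda c: (-len(c.seq), c.seq, -len(c.constituents), c.evalue, c.id),
    )
    kept: list[Contig] = []
    kept_seqs: list[str] = []
    for c in order:
        if any(c.seq in s for s in kept_seqs):
            continue
        kept.append(c)
        kept_seqs.append(c.seq)
    kept = [c for c in kept if c.evalue <= scheme.evalue_max]
    kept.sort(key=lambda c: (c.evalue, -c.score, c.id))
    assigned = {rid for c in kept for rid, _ in c.constituents}
    unassigned = [rid for rid in range(len(reads)) if rid not in assigned]
    return SearchResult(kept, unassigned, scheme, query_id)


def recruit_reads(
    result: SearchResult, reads: ReadSet, max_mismatch: int = 2
) -> SearchResult:
    """Optional post-step: map leftover reads onto the reported contigs.

    A read is recruited when it fits entirely inside a contig with at most
    ``max_mismatch`` mismatches (ungapped).  Contig sequences are never
    altered; recruits are appended to constituent lists.
    """
    still: list[int] = []
    for rid in result.unassigned_reads:
        rseq = reads.seqs[rid]
        best: tuple[int, int, int] | None = None  # (mismatches, contig idx, offset)
        for ci, contig in enumerate(result.contigs):
            cseq = contig.seq
            for off in range(0, len(cseq) - len(rseq) + 1):
                mm = sum(a != b for a, b in zip(rseq, cseq[off : off + len(rseq)]))
                if mm <= max_mismatch and (best is None or mm < best[0]):
                    best = (mm, ci, off)
                    if mm == 0:
                        break
            if best is not None and best[0] == 0:
                break
        if best is None:
            still.append(rid)
        else:
            _, ci, off = best
            contig = result.contigs[ci]
            contig.constituents = tuple(
                sorted(set(contig.constituents) | {(rid, off)})
            )
            result.recruited.append((rid, ci, off))
    result.unassigned_reads = still
    return result
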