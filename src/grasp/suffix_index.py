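"""Generalized suffix array with LCP over the read set.

The assembler never builds an explicit read-overlap graph.  Read overlaps
are discovered on demand from two suffix arrays: a forward one over the
concatenated reads and a mirrored one over the reversed reads.  Supporting
reads for a growing assembly path (reads whose prefix equals a suffix of
the path, with overlap >= l) fall out of range queries on the reversed
array; maximal extension sequences fall out of a single LCP pass over the
forward array.

Reads are concatenated with a delimiter (``#``) that sorts below every
residue, so suffixes that begin inside a read never match a residue
pattern across a read boundary, and read-local suffixes that are prefixes
of longer matches sort to the front of their interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import ReadSet, SequenceError

DELIMITER = "#"


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), fully vectorised)."""
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        changed = np.ones(n, dtype=bool)
        r1, r2 = rank[order], key2[order]
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            break
        k *= 2
    return order.astype(np.int64)


def _lcp_kasai(text: str, sa: np.ndarray) -> np.ndarray:
    """LCP array (lcp[i] = LCP of suffixes sa[i-1], sa[i]); Kasai's algorithm."""
    n = len(text)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = int(sa[r - 1])
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


@dataclass(frozen=True)
class SupportingRead:
    """A read whose prefix (>= l residues) equals a suffix of the path.

    ``extension`` is the remaining, non-empty part of the read: the suffix
    beyond the overlap for right extension, the prefix before the overlap
    (in normal orientation) for left extension.
    """

    read_id: int
    overlap_len: int
    extension: str


@dataclass
class ExtensionCandidate:
    """A maximal extension sequence with its supporting-read weight."""

    extension: str
    supporting_read_ids: list[int]
    overlaps: list[int]  # parallel to supporting_read_ids

    @property
    def weight(self) -> int:
        return len(self.supporting_read_ids)


class SuffixIndex:
    """Generalized suffix array + LCP over a read set (or its reversal)."""

    def __init__(self, reads: ReadSet, reversed_flag: bool = False):
        if any(DELIMITER in s for s in reads.seqs):
            raise SequenceError(f"reads must not contain the delimiter {DELIMITER!r}")
        self.reads = reads
        self.reversed_flag = reversed_flag
        seqs = [s[::-1] for s in reads.seqs] if reversed_flag else list(reads.seqs)
        parts: list[str] = []
        starts = np.empty(len(seqs), dtype=np.int64)
        pos = 0
        for i, s in enumerate(seqs):
            starts[i] = pos
            parts.append(s)
            parts.append(DELIMITER)
            pos += len(s) + 1
        self.text = "".join(parts)
        self.read_starts = starts
        n = len(self.text)
        codes = np.frombuffer(self.text.encode("ascii"), dtype=np.uint8).astype(np.int64)
        self.sa = _suffix_array(codes)
        self.lcp = _lcp_kasai(self.text, self.sa)
        # position -> read index; delimiter positions belong to the preceding read
        self.pos_read = np.searchsorted(starts, np.arange(n), side="right") - 1
        ends = np.append(starts[1:], n) - 1  # delimiter position per read
        self.local_len = ends[self.pos_read] - np.arange(n)  # 0 at the delimiter itself

    def locate(self, pos: int) -> tuple[int, int]:
        """Map a text position to (read index, offset within the read)."""
        rid = int(self.pos_read[pos])
        return rid, pos - int(self.read_starts[rid])

    def suffix(self, pos: int) -> str:
        """Read-local suffix at a text position (stops at the delimiter)."""
        return self.text[pos : pos + int(self.local_len[pos])]

    # -- range queries ----------------------------------------------------

    def range_query(self, pattern: str, lo: int = 0, hi: int | None = None) -> tuple[int, int]:
        """Half-open SA interval of suffixes having ``pattern`` as prefix.

        Binary search, O(|pattern| log |sa|); an optional [lo, hi) restricts
        the search to a previously returned interval.
        """
        if not pattern:
            raise ValueError("pattern must be non-empty")
        if hi is None:
            hi = len(self.sa)
        text, sa, m = self.text, self.sa, len(pattern)
        a, b = lo, hi
        while a < b:  # first suffix >= pattern
            mid = (a + b) // 2
            if text[sa[mid] : sa[mid] + m] < pattern:
                a = mid + 1
            else:
                b = mid
        left = a
        b = hi
        while a < b:  # first suffix with prefix > pattern
            mid = (a + b) // 2
            if text[sa[mid] : sa[mid] + m] <= pattern:
                a = mid + 1
            else:
                b = mid
        return left, a


def build_index(reads: ReadSet, reversed_flag: bool = False) -> SuffixIndex:
    return SuffixIndex(reads, reversed_flag=reversed_flag)


def range_query(idx: SuffixIndex, pattern: str) -> tuple[int, int]:
    return idx.range_query(pattern)


def find_supporting_reads(
    fwd: SuffixIndex,
    rev_idx: SuffixIndex,
    p: str,
    l: int,
    direction: str = "right",
) -> list[SupportingRead]:
    """All reads able to extend path ``p`` in the given direction.

    Right extension: reads whose prefix of length o (l <= o <= |p|) equals
    the o-suffix of ``p`` and that continue beyond the overlap.  Discovery
    queries the reversed index with rev(x), x the l-suffix of p, then
    narrows the interval by binary search for successively longer prefixes
    of rev(p); at each overlap length o the reads whose reversed-read
    suffix is exactly rev(p)[:o] sit at the front of the interval (the
    delimiter sorts lowest).  Left extension is the mirror case.
    """
    if direction not in ("right", "left"):
        raise ValueError(f"direction must be 'right' or 'left', got {direction!r}")
    if len(p) < l:
        raise ValueError(f"path length {len(p)} < overlap cutoff l={l}")
    if direction == "right":
        # read prefixes vs path suffixes: probe the reversed index with
        # growing prefixes of rev(p); the extension is the read's tail.
        idx, probe = rev_idx, p[::-1]
    else:
        # read suffixes vs path prefixes: probe the forward index with
        # growing prefixes of p; the extension is the read's head.
        idx, probe = fwd, p

    reads = idx.reads
    out: list[SupportingRead] = []
    i, j = idx.range_query(probe[:l])
    o = l
    while i < j:
        # entries whose whole read-local suffix equals probe[:o] sort first
        while i < j and int(idx.local_len[idx.sa[i]]) == o:
            rid, _ = idx.locate(int(idx.sa[i]))
            seq = reads.seqs[rid]
            ext = seq[o:] if direction == "right" else seq[: len(seq) - o]
            if ext:
                out.append(SupportingRead(rid, o, ext))
            i += 1
        o += 1
        if o > len(p) or i >= j:
            break
        i, j = idx.range_query(probe[:o], i, j)
    out.sort(key=lambda s: (s.read_id, s.overlap_len))
    return out


def maximal_extensions(
    fwd: SuffixIndex,
    p: str,
    l: int,
    supporting: list[SupportingRead],
) -> list[ExtensionCandidate]:
    """Prune supporting reads to maximal extension sequences.

    A candidate extension is maximal when it is not a proper substring of
    any other extension for the same path.  Detection walks the
    lexicographic interval of the forward array for x (the l-suffix of p)
    once: a supporting-read suffix is maximal iff its (read-local) LCP with
    the next supporting-read suffix in the ordering is shorter than its own
    extension-bearing length.  That pass eliminates proper prefixes; a
    final substring filter over the few survivors completes proper-substring
    maximality.  The weight of a maximal extension counts the supporting
    reads it subsumes (those whose extension is one of its prefixes), i.e.
    exactly the reads contained in the extended path.
    """
    if not supporting:
        return []
    x = p[-l:]
    i, j = fwd.range_query(x)
    want = {}
    for s in supporting:
        rid_start = int(fwd.read_starts[s.read_id])
        want[rid_start + s.overlap_len - l] = s  # text position of x . extension
    marked: list[tuple[int, SupportingRead]] = []  # (sa rank, supporting read)
    for t in range(i, j):
        pos = int(fwd.sa[t])
        if pos in want:
            marked.append((t, want[pos]))
    survivors: list[SupportingRead] = []
    for a in range(len(marked)):
        t1, s1 = marked[a]
        own = l + len(s1.extension)  # read-local suffix length of this entry
        if a + 1 < len(marked):
            t2, s2 = marked[a + 1]
            raw = int(self_min(fwd.lcp, t1 + 1, t2 + 1))
            eff = min(raw, own, l + len(s2.extension))
            if eff >= own:
                continue  # extension is a prefix of (or equal to) the next one
        survivors.append(s1)
    # complete the proper-substring partial order over the survivors
    exts = sorted({s.extension for s in survivors}, key=lambda e: (-len(e), e))
    kept: list[str] = []
    for e in exts:
        if not any(e in other for other in kept):
            kept.append(e)
    out = []
    for e in kept:
        subs = [s for s in supporting if e.startswith(s.extension)]
        subs.sort(key=lambda s: (s.read_id, s.overlap_len))
        out.append(
            ExtensionCandidate(e, [s.read_id for s in subs], [s.overlap_len for s in subs])
        )
    out.sort(key=lambda c: (-len(c.extension), c.extension))
    return out


def self_min(arr: np.ndarray, lo: int, hi: int) -> int:
    """Minimum of arr[lo:hi] (the LCP of two suffixes at SA ranks lo-1, hi-1)."""
    return int(arr[lo:hi].min()) if hi > lo else 0
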