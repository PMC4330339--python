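"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — plain definitions, no shared code
with the package internals — so agreement is meaningful.
"""

from __future__ import annotations

from grasp.scoring import NEG_INF, ScoringScheme


def naive_suffix_array(text: str) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_lcp(text: str, sa: list[int]) -> list[int]:
    out = [0] * len(sa)
    for i in range(1, len(sa)):
        a, b = text[sa[i - 1] :], text[sa[i] :]
        n = 0
        while n < min(len(a), len(b)) and a[n] == b[n]:
            n += 1
        out[i] = n
    return out


def brute_pattern_positions(reads: list[str], pattern: str) -> list[tuple[int, int]]:
    """All (read, offset) where pattern occurs — read-local substring scan."""
    hits = []
    for rid, seq in enumerate(reads):
        for off in range(len(seq) - len(pattern) + 1):
            if seq[off : off + len(pattern)] == pattern:
                hits.append((rid, off))
    return hits


def brute_supporting(
    reads: list[str], p: str, l: int, direction: str
) -> set[tuple[int, int, str]]:
    """(read, overlap, extension) triples straight from the definition."""
    out = set()
    for rid, seq in enumerate(reads):
        for o in range(l, min(len(p), len(seq)) + 1):
            if direction == "right":
                if seq[:o] == p[len(p) - o :] and seq[o:]:
                    out.add((rid, o, seq[o:]))
            else:
                if seq[len(seq) - o :] == p[:o] and seq[: len(seq) - o]:
                    out.add((rid, o, seq[: len(seq) - o]))
    return out


def brute_maximal(extensions: set[str]) -> set[str]:
    """Maximal elements under the proper-substring partial order."""
    return {
        e
        for e in extensions
        if not any(e != f and e in f for f in extensions)
    }


def brute_banded(p: str, q: str, scheme: ScoringScheme) -> int | None:
    """From-scratch banded global affine alignment, dict-of-cells DP."""
    h = scheme.half_band
    go, ge = scheme.gap_open, scheme.gap_extend
    I, J = len(p), len(q)
    if abs(I - J) > h:
        return None
    M: dict = {}
    X: dict = {}
    Y: dict = {}
    for i in range(I + 1):
        for j in range(max(0, i - h), min(J, i + h) + 1):
            if i == 0 and j == 0:
                M[0, 0], X[0, 0], Y[0, 0] = 0, NEG_INF, NEG_INF
                continue
            m = x = y = NEG_INF
            if i > 0 and j > 0 and (i - 1, j - 1) in M:
                m = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + scheme.sub(
                    p[i - 1], q[j - 1]
                )
            if i > 0 and (i - 1, j) in M:
                x = max(max(M[i - 1, j], Y[i - 1, j]) - go - ge, X[i - 1, j] - ge)
            if j > 0 and (i, j - 1) in M:
                y = max(max(M[i, j - 1], X[i, j - 1]) - go - ge, Y[i, j - 1] - ge)
            M[i, j], X[i, j], Y[i, j] = m, x, y
    if (I, J) not in M:
        return None
    s = max(M[I, J], X[I, J], Y[I, J])
    return None if s <= NEG_INF // 2 else s
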