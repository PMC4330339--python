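"""Seed-pair enumeration in reduced-alphabet space.

Assembly is initiated from pairs of highly similar k-mers, one from the
query and one from a database read.  Similarity is decided in two stages:
the k-mers must be identical after reduced-alphabet substitution, and
their ungapped score under the full-alphabet substitution matrix must
reach ``seed_score_min``.  The first stage is a hash-table lookup over all
read k-mers keyed by reduced form; the second weeds out class-mates that
are nevertheless poor matches.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import ReducedAlphabet
from .scoring import ScoringScheme, ungapped_score
from .seqio import ProteinSequence, ReadSet


@dataclass(frozen=True)
class SeedPair:
    """A (query k-mer, read k-mer) pair that initiates assembly."""

    q_pos: int
    read_id: int
    r_pos: int
    k: int
    seed_score: int
    q_kmer: str
    r_kmer: str


def build_reduced_kmer_table(
    reads: ReadSet, k: int, alphabet: ReducedAlphabet
) -> dict[str, list[tuple[int, int]]]:
    """Hash table: reduced k-mer -> all (read index, offset) occurrences."""
    if k < 3:
        raise ValueError("k must be >= 3")
    table: dict[str, list[tuple[int, int]]] = {}
    for rid, seq in enumerate(reads.seqs):
        if len(seq) < k:
            continue
        red = alphabet.reduce(seq)
        for off in range(len(seq) - k + 1):
            table.setdefault(red[off : off + k], []).append((rid, off))
    return table


def enumerate_seeds(
    query: ProteinSequence,
    table: dict[str, list[tuple[int, int]]],
    scheme: ScoringScheme,
    alphabet: ReducedAlphabet,
    reads: ReadSet,
) -> list[SeedPair]:
    """All seed pairs, ordered by (q_pos, read_id, r_pos)."""
    k = scheme.k
    if len(query) < k:
        raise ValueError(f"query {query.id!r} shorter than k={k}")
    q = query.residues
    red_q = alphabet.reduce(q)
    seeds: list[SeedPair] = []
    for q_pos in range(len(q) - k + 1):
        hits = table.get(red_q[q_pos : q_pos + k])
        if not hits:
            continue
        q_kmer = q[q_pos : q_pos + k]
        for rid, off in hits:
            r_kmer = reads.seqs[rid][off : off + k]
            score = ungapped_score(q_kmer, r_kmer, scheme)
            if score >= scheme.seed_score_min:
                seeds.append(SeedPair(q_pos, rid, off, k, score, q_kmer, r_kmer))
    seeds.sort(key=lambda s: (s.q_pos, s.read_id, s.r_pos))
    return seeds
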