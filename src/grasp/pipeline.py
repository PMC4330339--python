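"""End-to-end homolog search: seed, extend, merge, dedupe, report.

The unit of parallelism is the seed pair: extensions from different seeds
are independent (each carries its own redundancy table), and their contig
lists are concatenated in seed order before deduplication, so results are
identical for any thread count.
"""

from __future__ import annotations

import hashlib
import json
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path

from . import __version__
from .alphabet import ReducedAlphabet
from .extension import RedundancyTable, extend_direction
from .merge import Contig, SearchResult, dedupe_contigs, merge_paths, recruit_reads
from .scoring import ScoringScheme
from .seeding import SeedPair, build_reduced_kmer_table, enumerate_seeds
from .seqio import ProteinSequence, ReadSet
from .suffix_index import SuffixIndex, build_index


class SearchIndex:
    """Forward/reverse suffix indexes plus the reduced k-mer table."""

    def __init__(self, reads: ReadSet, scheme: ScoringScheme, alphabet: ReducedAlphabet):
        self.reads = reads
        self.fwd = build_index(reads, reversed_flag=False)
        self.rev = build_index(reads, reversed_flag=True)
        self.kmer_table = build_reduced_kmer_table(reads, scheme.k, alphabet)


def _search_one_seed(
    seed: SeedPair,
    query: ProteinSequence,
    reads: ReadSet,
    idx: SearchIndex,
    scheme: ScoringScheme,
    log=None,
) -> list[Contig]:
    redundancy = RedundancyTable()
    rights = extend_direction(
        seed, "right", query, reads, idx.fwd, idx.rev, scheme, redundancy, log=log
    )
    lefts = extend_direction(
        seed, "left", query, reads, idx.fwd, idx.rev, scheme, redundancy, log=log
    )
    return merge_paths(
        lefts, rights, seed, scheme, idx.fwd, reads, query.id, len(query)
    )


def search(
    query: ProteinSequence,
    reads: ReadSet,
    scheme: ScoringScheme | None = None,
    alphabet: ReducedAlphabet | None = None,
    index: SearchIndex | None = None,
    recruit: bool = False,
    max_mismatch: int = 2,
    threads: int = 1,
    log=None,
) -> SearchResult:
    """Identify homologs of ``query`` in the short-peptide database.

    Returns a substring-free set of contigs with E-value <=
    ``scheme.evalue_max``, each carrying its constituent reads.
    """
    scheme = scheme if scheme is not None else ScoringScheme()
    alphabet = alphabet if alphabet is not None else ReducedAlphabet.preset("murphy10")
    scheme = scheme.with_db(reads.total_residues)
    idx = index if index is not None else SearchIndex(reads, scheme, alphabet)
    seeds = enumerate_seeds(query, idx.kmer_table, scheme, alphabet, reads)
    contigs: list[Contig] = []
    if threads <= 1 or len(seeds) < 2:
        for seed in seeds:
            contigs.extend(_search_one_seed(seed, query, reads, idx, scheme, log=log))
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            futures = [
                pool.submit(_search_one_seed, seed, query, reads, idx, scheme, log)
                for seed in seeds
            ]
            for fut in futures:  # deterministic: collected in seed order
                contigs.extend(fut.result())
    result = dedupe_contigs(contigs, scheme, reads, query.id)
    if recruit:
        result = recruit_reads(result, reads, max_mismatch=max_mismatch)
    return result


def best_single_read_evalue(
    query: ProteinSequence,
    reads: ReadSet,
    scheme: ScoringScheme | None = None,
    alphabet: ReducedAlphabet | None = None,
) -> float | None:
    """Best E-value any *individual* read achieves against the query.

    Each read is scored on its own — a banded global alignment against the
    query window on its best seed diagonal, under the same matrix, band
    and Karlin-Altschul statistics as the assembly search — so the number
    is directly comparable with contig E-values.  None when no read has a
    seed at all.
    """
    from .banded import banded_score
    from .merge import evalue as _evalue

    scheme = scheme if scheme is not None else ScoringScheme()
    alphabet = alphabet if alphabet is not None else ReducedAlphabet.preset("murphy10")
    scheme = scheme.with_db(reads.total_residues)
    table = build_reduced_kmer_table(reads, scheme.k, alphabet)
    seeds = enumerate_seeds(query, table, scheme, alphabet, reads)
    best_score: dict[int, int] = {}
    for seed in seeds:
        rseq = reads.seqs[seed.read_id]
        c0 = seed.q_pos - seed.r_pos  # diagonal through the seed
        a = max(0, c0)
        b = min(len(query), c0 + len(rseq))
        if b <= a:
            continue
        qwin = query.residues[a:b]
        score = banded_score(rseq, qwin, scheme)
        if score is None:
            continue
        if score > best_score.get(seed.read_id, -(10**9)):
            best_score[seed.read_id] = score
    if not best_score:
        return None
    return min(_evalue(s, len(query), scheme) for s in best_score.values())


def identified_read_ids(result: SearchResult, reads: ReadSet) -> set[str]:
    """Read ids assigned to any reported contig (constituents + recruits)."""
    out = set()
    for contig in result.contigs:
        for rid, _ in contig.constituents:
            out.add(reads.ids[rid])
    return out


# -- reporting -----------------------------------------------------------


def contig_table_rows(result: SearchResult, reads: ReadSet) -> list[dict]:
    """One row per contig; query coordinates 1-based inclusive."""
    rows = []
    for c in result.contigs:
        rows.append(
            {
                "contig_id": c.id,
                "query_id": c.query_id,
                "q_start": c.q_start + 1,
                "q_end": c.q_end,
                "score": c.score,
                "evalue": f"{c.evalue:.3g}",
                "n_reads": c.n_reads,
                "contig_seq": c.seq,
            }
        )
    return rows


def write_contig_tsv(path: str | Path, result: SearchResult, reads: ReadSet) -> None:
    cols = ["contig_id", "query_id", "q_start", "q_end", "score", "evalue", "n_reads", "contig_seq"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in contig_table_rows(result, reads):
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def write_read_tsv(path: str | Path, result: SearchResult, reads: ReadSet) -> None:
    """Read-to-contig assignment table (offset 1-based)."""
    recruited = {(rid, ci) for rid, ci, _ in result.recruited}
    with open(path, "w") as fh:
        fh.write("read_id\tcontig_id\toffset\trecruited\n")
        for ci, contig in enumerate(result.contigs):
            for rid, off in contig.constituents:
                flag = int((rid, ci) in recruited)
                fh.write(f"{reads.ids[rid]}\t{contig.id}\t{off + 1}\t{flag}\n")


def write_contig_fasta(path: str | Path, result: SearchResult) -> None:
    from .seqio import write_fasta

    write_fasta(path, [(c.id, c.seq) for c in result.contigs])


def write_manifest(path: str | Path, params: dict, inputs: dict[str, str | Path]) -> None:
    """Run manifest: parameters, input hashes and version, for reproducibility."""
    digest = {}
    for name, p in inputs.items():
        h = hashlib.sha256()
        h.update(Path(p).read_bytes())
        digest[name] = h.hexdigest()
    payload = {"version": __version__, "parameters": params, "input_sha256": digest}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
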