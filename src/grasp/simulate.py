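"""Synthetic read simulation and benchmark evaluation.

The simulator emulates the construction of the protein-family benchmark
databases: short peptide reads (default 32 residues) are sampled from
full-length source proteins by a homogeneous Poisson process at a target
fold-coverage (default 20X), and searches are evaluated leave-one-out —
all reads sampled from the query's own source sequence are removed from
the database before searching.

A read is a true homolog iff it was sampled from a member of the query's
family; sensitivity is TP/(TP+FN) and specificity TP/(TP+FP) over the
identified read set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, ProteinSequence, SequenceError


@dataclass
class SimConfig:
    """Fragment-sampling conditions (32-residue reads at 20X coverage)."""

    read_len: int = 32
    coverage: float = 20.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass(frozen=True)
class TruthLabel:
    source_id: str
    start: int
    family: str


@dataclass
class LabeledReads:
    """Simulated reads plus generator truth, the benchmark ground truth."""

    reads: list[tuple[str, str]]  # (read_id, residues)
    truth: dict[str, TruthLabel]

    def __add__(self, other: "LabeledReads") -> "LabeledReads":
        return LabeledReads(self.reads + other.reads, {**self.truth, **other.truth})

    def read_ids_from(self, source_ids: set[str]) -> set[str]:
        return {rid for rid, lab in self.truth.items() if lab.source_id in source_ids}

    def family_read_ids(self, family: str) -> set[str]:
        return {rid for rid, lab in self.truth.items() if lab.family == family}


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    sen: float | None
    spe: float | None


def sample_fragments(
    source: ProteinSequence,
    cfg: SimConfig,
    family: str = "",
    rng: np.random.Generator | None = None,
) -> LabeledReads:
    """Poisson-process fragment sampling from one source sequence.

    Fragment starts arrive at rate coverage/read_len per residue, so the
    expected read count is coverage * |source| / read_len.  Starts whose
    read would overrun the sequence end are redrawn within the valid
    range, keeping every read exactly ``read_len`` residues.
    """
    L = len(source)
    if L < cfg.read_len:
        raise SequenceError(
            f"source {source.id!r} ({L} aa) shorter than read_len={cfg.read_len}"
        )
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    n = int(rng.poisson(cfg.coverage * L / cfg.read_len))
    starts = np.sort(rng.integers(0, L - cfg.read_len + 1, size=n))
    reads, truth = [], {}
    for i, s in enumerate(starts):
        s = int(s)
        rid = f"{source.id}:{s}:{i}"
        reads.append((rid, source.residues[s : s + cfg.read_len]))
        truth[rid] = TruthLabel(source.id, s, family or source.id)
    return LabeledReads(reads, truth)


def leave_one_out(
    labeled: LabeledReads,
    query_source_id: str,
    known_sources: set[str] | None = None,
) -> LabeledReads:
    """Remove exactly the reads sampled from the query's own source.

    ``known_sources`` lets callers whose source catalogue is wider than
    the sampled reads validate the id; by default the sources seen in the
    truth labels are the catalogue.
    """
    catalogue = known_sources if known_sources is not None else {
        lab.source_id for lab in labeled.truth.values()
    }
    if query_source_id not in catalogue:
        raise KeyError(f"unknown source id {query_source_id!r}")
    keep = [(rid, seq) for rid, seq in labeled.reads if labeled.truth[rid].source_id != query_source_id]
    truth = {rid: lab for rid, lab in labeled.truth.items() if lab.source_id != query_source_id}
    return LabeledReads(keep, truth)


def evaluate(
    predicted: set[str], truth_homologs: set[str], universe: set[str]
) -> BenchmarkResult:
    """Confusion counts over read identification."""
    if not predicted <= universe:
        raise ValueError("predicted read ids outside the database universe")
    tp = len(predicted & truth_homologs)
    fp = len(predicted - truth_homologs)
    fn = len(truth_homologs - predicted)
    sen = tp / (tp + fn) if tp + fn else None
    spe = tp / (tp + fp) if tp + fp else None
    return BenchmarkResult(tp, fp, fn, sen, spe)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _diverge(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Point-substitute each site with the given probability."""
    if divergence == 0:
        return seq
    chars = list(seq)
    hits = rng.random(len(chars)) < divergence
    for i in np.flatnonzero(hits):
        alternatives = [a for a in AMINO_ACIDS if a != chars[i]]
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def make_family_fixture(
    n_families: int = 3,
    members_per_family: int = 2,
    seq_len: int = 160,
    divergence: float = 0.0,
    cfg: SimConfig | None = None,
) -> tuple[list[ProteinSequence], LabeledReads]:
    """Synthetic protein families plus a labeled read database.

    Each family grows from an independent uniform-random root by per-site
    point substitution at the requested divergence; reads are then sampled
    from every member.  Three unrelated families mirror the layout of the
    simpler simulated benchmark database.
    """
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    cfg = cfg if cfg is not None else SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    queries: list[ProteinSequence] = []
    all_reads: LabeledReads | None = None
    for f in range(n_families):
        root = _random_protein(rng, seq_len)
        family = f"fam{f}"
        for m in range(members_per_family):
            member_seq = root if m == 0 else _diverge(root, divergence, rng)
            member = ProteinSequence(f"{family}_m{m}", member_seq)
            queries.append(member)
            part = sample_fragments(member, cfg, family=family, rng=rng)
            all_reads = part if all_reads is None else all_reads + part
    assert all_reads is not None
    return queries, all_reads


def evalue_sweep(
    contig_table: pd.DataFrame,
    truth_homologs: set[str],
    universe: set[str],
    cutoffs: tuple[float, ...] = (1e-10, 1e-8, 1e-6, 1e-4, 1e-2, 1.0, 10.0),
) -> pd.DataFrame:
    """Sensitivity/specificity over an E-value cutoff sweep.

    ``contig_table`` must have columns ``evalue`` and ``read_ids`` (an
    iterable of constituent read ids per contig).
    """
    rows = []
    for cut in cutoffs:
        predicted: set[str] = set()
        for _, row in contig_table.iterrows():
            if row["evalue"] <= cut:
                predicted |= set(row["read_ids"])
        res = evaluate(predicted & universe, truth_homologs, universe)
        rows.append(
            {
                "cutoff": cut,
                "tp": res.tp,
                "fp": res.fp,
                "fn": res.fn,
                "sen": res.sen,
                "spe": res.spe,
            }
        )
    return pd.DataFrame(rows)


def write_fixture(
    outdir: str | Path, queries: list[ProteinSequence], labeled: LabeledReads
) -> None:
    """Write reads FASTA + truth TSV + query FASTA for CLI consumption."""
    from .seqio import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "queries.fasta", [(q.id, q.residues) for q in queries])
    write_fasta(outdir / "reads.fasta", labeled.reads)
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("read_id\tsource_id\tstart\tfamily\n")
        for rid, lab in labeled.truth.items():
            fh.write(f"{rid}\t{lab.source_id}\t{lab.start}\t{lab.family}\n")
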