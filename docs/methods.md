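# Methods

## Problem and model

Given a query protein *Q* and a database *R* of short peptide reads
(partial-length protein fragments, e.g. gene-caller output on metagenomic
sequencing reads), the task is to report contigs — assemblies of exactly
overlapping reads — whose alignment to *Q* meets an E-value threshold. The
algorithm is a guided traversal of the implicit read-overlap graph: the
overlap graph is never built; read overlaps are discovered on demand from two
generalized suffix arrays (one over the concatenated reads, one over the
reversed reads), and the query steers which overlaps are worth following.

Assumptions worth making explicit:

* **Exact overlaps.** A read extends a path only if its prefix matches a
  path suffix *exactly* (length ≥ *l*). Sequencing or gene-calling errors
  inside the overlap break the chain; mismatch-tolerant overlaps are out of
  scope. Divergence between database *and query* is tolerated (that is what
  the banded alignment absorbs); divergence *among the database reads of one
  source region* is not.
* **A read may join multiple contigs**; redundancy is controlled per search
  (see termination) and by the final substring-free output rule.
* **E-value model.** The Karlin–Altschul form E = K·m·n·exp(−λS) with the
  standard gapped BLOSUM62(11/1) constants λ = 0.267, K = 0.041; *m* is the
  query length and *n* the total residue count of the searched database.
  These statistics are an approximation for assembled contigs; the package
  relies on them only for ordering and thresholding, which is what the test
  suite asserts.

## Data structures

**Generalized suffix array.** Reads are concatenated with `#` (sorts below
every residue) after each read. The suffix array is built by prefix doubling
(O(n log² n), vectorised in numpy) and validated against a naive sort in the
tests; the LCP array uses Kasai's algorithm. Because residue-only patterns
can never match `#`, delimiter-initial suffixes drop out of every biological
query, and read-local suffixes that are prefixes of longer matches sort to
the front of their interval — which is what the supporting-read scan exploits.

**Supporting reads.** For right extension of path *p*, the reversed index is
queried with rev(x), x the *l*-suffix of *p*; the interval is then narrowed by
range-restricted binary search for successively longer prefixes of rev(p).
At match length *o*, the entries whose whole read-local suffix equals
rev(p)[:o] sit at the front of the interval: exactly the reads with overlap
*o*. Reads wholly contained in the path (empty extension) cannot extend and
are skipped. Left extension is the mirror image (read suffixes vs path
prefixes on the forward index).

**Maximal extensions.** Extensions that are proper substrings of another
extension of the same path are pruned. The single LCP pass over the interval
of x eliminates proper prefixes (LCP with the next supporting suffix ≥ own
length); a substring filter over the few survivors completes maximality under
the full proper-substring order, so the result matches the brute-force
definition exactly. The weight of a maximal extension counts the supporting
reads whose extension is one of its prefixes — precisely the reads contained
in the extended path, which keeps the constituent-containment invariant true
by construction.

## Alignment

Banded global Needleman–Wunsch with affine gaps (cost open + g·extend,
NCBI convention), three DP layers, band |i − j| ≤ d/2 anchored on the seed
diagonal. The query window is kept d/2 residues ahead of the path
(|q′| = |p′| + d/2, truncated at the query end), so extensions rarely hit the
band edge; a candidate whose end cell leaves the band is rejected, not an
error. After each extension only the band's last row and column (O(d) cells,
all three layers) plus the trailing 2·(d/2) characters of both sequences are
retained; the next extension fills only the new L-shaped region. The chain of
incremental updates reproduces the from-scratch banded DP of the final pair
*exactly* (integer equality, asserted against an independent implementation).

Two consequences of the window-ahead geometry are intentional: intermediate
path scores carry the gap penalty of the d/2 query overhang (a constant
offset, irrelevant to drop-off comparisons), and right extension terminates
when the *window* reaches the query end, i.e. the assembled path may stop up
to d/2 residues short of the query end for one seed — seeds closer to the
sequence end cover the remainder.

## Extension control

* **Priority.** Candidates are expanded heaviest-first; ties break on longer
  extension, then lexicographic extension, then insertion order — a total
  order, so output is independent of scheduling.
* **Sequence exhaustion.** No candidates are generated once the query window
  reaches the query end or no supporting read exists.
* **Score drop-off** (default X = 30): a candidate scoring below the best
  score on its own path chain minus X is abandoned. The paper-style separate
  acceptance threshold is folded into this rule. Reported paths are truncated
  to the best-scoring state on their chain (ties prefer the longer state).
* **Redundant extension.** A per-seed hash of (read, nominal query position
  of the read start) pairs; a candidate all of whose supporting reads were
  already consumed at the same query position is dropped, surviving
  candidates register their reads. The table is cleared between seeds so one
  seed's assembly cannot suppress another's legitimate contig. The nominal
  query position is the diagonal projection (path offset plus the path's
  query anchor); gap-induced shifts of a few residues only make the
  redundancy test slightly conservative.
* **Bootstrap below l.** A fresh seed path has length k < l, where no read
  can overlap by l; until |p| ≥ l the overlap requirement is min(|p|, l),
  which (combined with overlap ≤ |p|) means a read must start exactly at the
  path start. Reads straddling the seed k-mer are *not* reachable by either
  phase; they enter contigs as bridging reads at merge time.

## Merging and output

Bridging reads for a seed are found from the suffix-array interval of s^T:
an occurrence at read offset t bridges paths (L, R) when read[:t+k] is a
suffix of L and read[t:] is a prefix of R. Left/right path sets sharing the
same bridging-read set (≥ min_bridge, default 1) are ranked by score
(descending; the rank criterion is an interpretation — only "same rank are
paired" is prescribed) and same-rank pairs concatenated with score
score_L + score_R − ungapped seed score; bridging reads join the constituent
list. Unmerged paths pass through individually. Across all seeds, contigs are
deduplicated to a substring-free set (ties: more constituents, then lower
E-value, then smallest id) and then filtered at evalue_max. Coordinates are
0-based half-open internally and 1-based inclusive in all written tables.

The optional recruitment step (off by default) maps each unassigned read onto
the reported contigs, accepting full containment with at most max_mismatch
mismatches (fewest mismatches, then first contig, leftmost offset); contig
sequences never change.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| matrix | BLOSUM62 | standard protein search matrix |
| gap open / extend | 11 / 1 | standard BLOSUM62 pairing; gap of length g costs 11 + g |
| k | 6 | seed k-mer length; BLAST-like word seeding |
| seed_score_min | 11 | ungapped full-alphabet seed threshold (BLAST word threshold) |
| l | 10 | minimum read/path overlap; the stringent overlap criterion of the method |
| d | 40 | band size (half-width 20) — generous for 32-aa reads |
| dropoff | 30 | BLAST-like X-drop |
| min_bridge | 1 | most permissive reading of "enough bridging reads" |
| evalue_max | 10 | report cutoff |
| λ, K | 0.267, 0.041 | gapped BLOSUM62(11/1) Karlin–Altschul constants |

The default reduced alphabet is the Murphy 10-class partition
({LVIM}, {C}, {A}, {G}, {ST}, {P}, {FYW}, {EDNQ}, {KR}, {H}), a
well-characterised 10-letter alphabet with documented class membership; any
residue→representative TSV is accepted, so other published 10-class schemes
can be dropped in without code changes. `X` always forms its own class and
scores the matrix minimum against everything, so ambiguity codes from gene
callers neither seed nor reward extensions.

## Simulator

`make_family_fixture` emulates the family-benchmark layout: independent
uniform-random root sequences (one per family), members derived by per-site
point substitution at a chosen divergence, and 32-aa reads sampled from each
member by a homogeneous Poisson process at 20X expected coverage (read count
~ Poisson(coverage·L/read_len); starts uniform over the valid range, so
overrunning starts are effectively redrawn and every read keeps its full
length). Searches are evaluated leave-one-out: reads sampled from the query's
own source are removed first. A read is a true homolog iff sampled from a
member of the query's family.

What the simulator does **not** model: realistic residue composition or
indel divergence within families, sequencing errors inside reads,
gene-calling artifacts, and realistic database scale. Passing the noiseless
benchmark therefore demonstrates the correctness of the search/assembly
machinery under the stated conditions, not field performance on real
metagenomes.

Problem sizes used by the self-checks (chosen to exercise every code path at
desk scale): three 160-residue families of two members at 20X (~500 reads
after leave-one-out) for the recovery benchmark; one 200-residue pair at 25%
divergence and 2X for the assembly-gain comparison; 80-residue sources for
the determinism runs; 100 random read sets (≤ 50 reads × ≤ 40 aa) for the
index oracles.

## Numerical and design notes

* All DP scores are integers; "unreachable" cells use a −10⁹ sentinel, far
  below any reachable score yet overflow-safe under Python integers.
* The seed path is initialised with the banded-DP score of s^T vs s^Q; with
  the default scheme this equals the ungapped seed score (a gapped detour
  inside a 6-mer cannot pay for 11+1), which merging subtracts.
* A popped candidate extends its recorded parent path (the path whose
  supporting-read search produced it).
* Drop-off compares against the best score of the same path chain, not the
  best across the whole seed search, so one strong branch cannot starve an
  independent weaker branch.
* Parallelism (`--threads`) distributes seed searches; results are collected
  in seed order, so output is identical for any thread count. Within
  CPython's GIL, threading mainly overlaps numpy work; it is provided for
  API completeness and determinism is guaranteed rather than speedup.
* Duplicate seeds are not suppressed at seeding time; identical contigs from
  different seeds collapse in the final dedup.

## Known limitations

* Exact-overlap assembly fragments contigs at any intra-source mismatch;
  the recruitment step recovers some of the loss.
* Karlin–Altschul statistics with fixed gapped constants are approximate for
  short queries and for assembled contigs (no edge-effect or length
  corrections).
* The per-seed cost grows with coverage (each seed re-walks its
  neighbourhood); very deep databases benefit from the index cache and
  threads but the algorithm remains slower than plain per-read search, by
  design.
* Single-read scoring (`best_single_read_evalue`) aligns each read on its
  seed diagonal window; reads hanging off the query ends are scored against
  the truncated window.
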