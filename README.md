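# grasp — reference-guided search and assembly of short peptide reads

Metagenomic gene callers emit mostly *partial-length* protein sequences
("short peptides", typically ~30 aa), because genes are predicted directly on
short sequencing reads or on fragmented assemblies. Searching a reference
protein against such a database one read at a time is insensitive: a 32-residue
fragment of a genuine homolog often cannot reach a significant E-value on its
own, even when the full-length protein aligns convincingly.

`grasp` identifies the homologs of a query protein *Q* in a database *R* of
short peptide reads by **assembling overlapping reads into contigs while
searching**. Shotgun sequencing covers each protein with many overlapping
fragments, and amino-acid conservation makes exact peptide overlaps reliable;
a contig assembled from those fragments aligns to the query with a far better
E-value than any constituent read. Each output contig is either a single read
or an assembly in which every constituent read is an exact substring; the
reported contig set is substring-free (no contig is contained in another).

## Method in brief

* **Seeding.** All k-mer pairs (s^Q, s^T) — one k-mer from the query, one
  from a read — that are identical after reduced-alphabet substitution
  f: Σ → Σ* and whose ungapped substitution-matrix score reaches a threshold,
  enumerated via a hash table of reduced read k-mers.
* **Guided extension.** From each seed, paths are grown rightward (toward the
  query C-terminus) and then leftward. A *supporting read* for path *p* is a
  read whose prefix of length ≥ *l* equals a suffix of *p*; its remainder is
  an *extension sequence*. Supporting reads are found with a generalized
  suffix array over the reads (and one over the reversed reads), and pruned
  to *maximal* extension sequences with a single pass over the LCP array. A
  priority queue expands the heaviest extension (most supporting reads)
  first.
* **Banded alignment with boundary carry-over.** Each extended path p′ is
  aligned to the extended query window q′ by a banded Needleman–Wunsch with
  affine gaps; only the new DP cells are filled, resuming from the O(d)
  boundary scores stored at the previous step. Extension stops on sequence
  exhaustion, BLAST-style score drop-off, or redundant extension.
* **Merging and statistics.** Left and right paths are concatenated when
  bridging reads (containing s^T with flanks matching both paths) license
  the junction; the merged score is score_L + score_R − seed score. E-values
  follow the Karlin–Altschul form E = K·m·n·e^(−λS). Contigs are deduplicated
  to a substring-free set and filtered at the E-value cutoff.

A simulation module reproduces the benchmark protocol used to evaluate this
kind of search: 32-aa reads sampled from family members by a Poisson process
at 20X coverage, leave-one-out removal of reads from the query's own source,
and sensitivity/specificity (TP/(TP+FN), TP/(TP+FP)) over the identified
reads across an E-value sweep.

## Worked example

Simulate three unrelated families (two members each, 10% within-family
divergence, 20X coverage of 32-aa reads), search one member against the
leave-one-out database, and score against the generator truth:

```bash
grasp simulate --out demo --families 3 --members 2 --length 160 \
               --divergence 0.1 --seed 11
# build the leave-one-out database: drop reads sampled from fam0_m0 itself
python - <<'EOF'
from grasp.seqio import load_fasta, write_fasta
q0 = load_fasta("demo/queries.fasta")[0]
reads = load_fasta("demo/reads.fasta")
write_fasta("demo/db.fasta", [(p.id, p.residues) for p in reads
                              if not p.id.startswith(q0.id + ":")])
write_fasta("demo/query.fasta", [(q0.id, q0.residues)])
EOF
grasp search --query demo/query.fasta --db demo/db.fasta --out demo/run
grasp evaluate --contigs demo/run/fam0_m0.contigs.tsv \
               --reads-tsv demo/run/fam0_m0.reads.tsv \
               --truth demo/truth.tsv --query-source fam0_m0 \
               --out demo/sweep.tsv
```

The search prints `fam0_m0: 2 contigs`; the contig table starts

```
contig_id               query_id  q_start  q_end  score  evalue   n_reads
fam0_m0|s152.100.26|c0  fam0_m0   1        158    806    3.8e-89  98
fam0_m0|s0.0.0|c0       fam0_m0   1        160    772    3.33e-85 97
```

— two contigs spanning essentially the whole 160-residue query, assembled
from ~100 of the 523 database reads, at E-values around 10⁻⁸⁵ (a single
32-aa read cannot come near this). The evaluation sweep reports

```
      cutoff  tp  fp  fn  sen  spe
1.000000e-10 101   0   0  1.0  1.0
...
1.000000e+01 101   0   0  1.0  1.0
```

all 101 reads sampled from the homologous family member are recovered and no
read from the two unrelated families is reported, at every cutoff from 10⁻¹⁰
to 10.

## Library layout

| module | contents |
| --- | --- |
| `grasp.seqio` | FASTA I/O, `ProteinSequence`, `ReadSet`, reversal |
| `grasp.alphabet` | reduced amino-acid alphabets (`murphy10` preset, TSV loader) |
| `grasp.scoring` | `ScoringScheme`: matrix, gaps, seeding/band/E-value parameters |
| `grasp.suffix_index` | generalized suffix array + LCP, supporting reads, maximal extensions |
| `grasp.seeding` | reduced-alphabet k-mer table and seed-pair enumeration |
| `grasp.banded` | incremental banded Needleman–Wunsch with boundary carry-over |
| `grasp.extension` | priority-queue guided assembly with the three termination criteria |
| `grasp.merge` | bridging reads, path merging, E-values, substring-free dedup, read recruitment |
| `grasp.pipeline` | `search()` orchestration, single-read baseline, TSV/manifest writers |
| `grasp.simulate` | Poisson fragment simulator, leave-one-out, sensitivity/specificity |
| `grasp.cli` | `grasp index / search / simulate / evaluate` |

See `docs/methods.md` for the model, parameter and design notes.
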