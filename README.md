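# ltrlayers

Reconstruction of structurally complex and nested LTR retrotransposons from
repeat-library alignments against a genome.

Starting from a consensus library (FASTA entries named `<family>_LTR` and
`<family>_IN`) and a RepeatMasker-format `.out` alignment table, the pipeline

1. filters and de-overlaps alignment fragments (higher score wins, losers
   are trimmed or dropped),
2. merges adjacent split hits of the same family into candidate LTR/IN
   pieces,
3. links candidates with a four-branch decision procedure (LTR-LTR, IN-IN,
   LTR-IN, IN-LTR) assigning pairwise states 0 = not linked, 1 = linked,
   2 = inserted,
4. grows dynamic link lists (chains) and recursively re-links the inserted
   pool, so elements of layer *i* are interrupted only by elements of layer
   *i*+1,
5. names each chain's structural type (`LTR-IN-LTR`, `LTR`, `IN-LTR`,
   `LTR-IN-LTR-IN-LTR`, ...) and maps it to one of five categories (Normal,
   SoloLTR, Complex, Truncated, Others), and
6. dates elements with two or more LTRs from intra-element LTR divergence
   using the Kimura two-parameter distance, `T = K / (2r)`, at both
   1.3e-8 and 7e-9 substitutions/site/year.

A fully ground-truthed genome simulator (`ltrlayers simulate`) plants
full-length, solo-LTR, complex, truncated and multiply nested elements with
target-site duplications and emits exact `.out` alignments, so the whole
pipeline is testable without any external aligner.

## Command line

```bash
# generate a synthetic genome + library + alignments + ground truth
ltrlayers simulate --seed 1 --out-dir sim

# run the pipeline on the alignment table
ltrlayers run -i sim/library.fa -d sim/genome.fa -o sim/RM.out --out-dir out

# optional: collapse redundant library entries first
ltrlayers dedupe-library -i sim/library.fa --out dedup.fa
```

`run` accepts the classic flag set (`-i` library, `-d` genome, `-o`
alignment table, `-a` threads, `-D` max divergence 20, `-C` min score 600,
`-L` min length 100, `-s` min coverage 80, `-I` min identity 80) plus linker
and defragmentation tolerances (`--gap-tol`, `--cons-tol`, `--end-tol`,
`--g-direct`, `--g-insert`). `-P`/`-p` (external aligner paths) are accepted
for interface parity; the tested path consumes a precomputed `.out` table.

Outputs in `--out-dir`:

* `type.num.x` — copy number of each structural type at layer *x*;
* `type.all.x` — one row per layer-*x* element with position, type,
  category, host and member pieces;
* `elements.gff3` — all elements with `Parent` attributes linking nested
  elements to their hosts;
* `ages.tsv` — P, Q, K and insertion times for dated LTR pairs;
* `stats.tsv` — per-stage counts and category rollups
  (`--table1-compat` folds Others into Truncated).

## Library API

```python
from ltrlayers import (
    parse_library_fasta, parse_repeatmasker_out,
    resolve_overlaps, merge_adjacent, resolve_layers,
    build_chains, link_state, summarize, estimate_age,
    SimConfig, simulate_genome, emit_alignments,
)
```

`build_chains` takes an injectable pairwise state function, so chain
construction can be driven by an explicit state matrix in tests.
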