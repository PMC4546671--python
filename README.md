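# tandemtract

Resolve the internal motif structure of long tandem nucleotide repeat
expansions from single-molecule long reads — at desk scale, end to end:

1. **simulate** expansion templates (ordered motif blocks between unique
   intronic flanks) and multi-pass single-molecule reads with an
   insertion-dominant error channel;
2. **filter** reads by length/quality (boundary-keeping initial filter,
   strict per-round assembly selectors, multi-pass selection by pass count
   and predicted accuracy);
3. **assemble** a draft contig by greedy overlap-layout-consensus and
   **polish** it through successive map-and-refine rounds (column-majority
   pileup over banded alignments, default two-round schedule
   `(>4000 nt, >0.85)` then `(>4500 nt, >0.80)`);
4. **decompose** the repeat tract into motif blocks by dynamic programming
   (minimise uncovered nucleotides, then block count, then prefer
   higher-priority motifs) and report per-motif composition statistics;
5. **verify** the consensus: local-alignment percent identity of the flanks
   and repeat ends against a reference, plus a block-level structural diff
   between two decompositions.

The default motif dictionary targets the intronic ATTCT pentanucleotide
expansion locus of *ATXN10* (canonical `ATTCT`; interruption motifs
`ATTTTCT, ATATTCT, ATTCTCT, ATTCTTCT, ATTCC, ATCCT, ATCCC`; minor motifs
`ACT, ATC, ATT, ATCT, ATTTCT, ATTTCC, ATCC`) and is fully configurable, so
any other repeat locus can be analysed by supplying a dictionary JSON.

## Command line

One subcommand per stage plus a one-shot run:

```sh
tandemtract run --out-dir out/                 # demo: simulate -> ... -> verify
tandemtract run --config my.cfg --seed 7 --out-dir out/

tandemtract simulate --out-dir sim/ --seed 3
tandemtract filter   --reads sim/reads.fasta --meta sim/reads.tsv \
                     --min-length 50 --min-quality 0.75 --out-prefix kept
tandemtract assemble --reads kept.fasta --meta kept.tsv --out draft.fasta
tandemtract polish   --reference draft.fasta --reads kept.fasta --meta kept.tsv \
                     --rounds 4000:0.85,4500:0.80 --out consensus.fasta
tandemtract decompose --fasta consensus.fasta --json comp.json --bed blocks.bed
tandemtract verify   --consensus consensus.fasta --reference template.fasta \
                     --flank5 @flank5.txt --flank3 @flank3.txt
```

Config files are flat `key = value` lines; values are parsed as JSON where
possible (`block_spec = [["ATTCT", 220], ["ATCCT", 1]]`). Every `run` writes
a `manifest.json` (parameters, versions, seed, artifact list) so results are
reproducible from the manifest alone. Outputs are plain text: FASTA, TSV,
BED-style block annotations, JSON composition summaries and a text
schematic (one glyph per block, 5'→3').

## Package layout

| module | contents |
| --- | --- |
| `tandemtract.simulate`  | templates, error channel + edit ledger, multi-pass read simulation, FASTA/TSV I/O |
| `tandemtract.reads`     | filter cascade, multi-pass selection, per-molecule consensus |
| `tandemtract.alignment` | banded global/semi-global aligner (numba), pileup consensus, vote-guided consensus refinement, local alignment (Biopython) |
| `tandemtract.assembly`  | greedy OLC draft, iterative map-and-polish refinement |
| `tandemtract.decompose` | motif dictionary, DP tract decomposition, composition statistics, tract location, BED/schematic export |
| `tandemtract.verify`    | percent-identity reports (flanks/repeat ends), structural diff of decompositions |
| `tandemtract.pipeline`  | orchestration, config files, manifest, `decompose_fasta` |
| `tandemtract.cli`       | click CLI (`tandemtract`) |

Coordinates are 0-based, half-open everywhere; all randomness flows from
explicit integer seeds.
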