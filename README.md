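# cpsweep

Reference-guided k-mer sweep optimisation for chloroplast (cp) genome
assembly.

Assembling an organelle genome from whole-genome Illumina reads is mostly a
parameter problem: de Bruijn-graph assemblers depend heavily on the k-mer
length k, and the "right" k is not knowable in advance.  `cpsweep`
implements a small, fully self-contained version of the classic
protocol for picking it empirically:

1. **Quality control** — truncate every read at its first base with Phred
   score < 13 (error probability 0.05) through the 3' end, then discard
   reads shorter than a minimum length (17, 21 or 25 by default).
2. **Assembly sweep** — assemble contigs at every odd k from 17 to 99
   (odd only: an even-length k-mer can equal its own reverse complement
   and bias canonical counting).  A minimal built-in de Bruijn unitig
   assembler makes the sweep runnable without external binaries; contigs
   from a production assembler can be supplied as FASTA instead.
3. **Length control** — remove contigs shorter than 150 bp.
4. **Homology search** — align contigs to a related reference cp genome
   with a built-in seed-and-extend local aligner (or parse external BLAST
   `-outfmt 6` tables), keep **only the best HSP per contig**, then keep
   HSPs with identity > 85% and length > 150 bp.
5. **Coverage scoring** — for each configuration `(min read length, k,
   HSP-length cutoff)`, report the fraction of reference positions covered
   by the union of retained HSP intervals:

   `coverage(c) = |union of subject intervals| / L_ref`

   The configuration grid is 3 x 42 = 126 points by default; the best k is
   the argmax of coverage.
6. **Finishing** — map read pairs back to the chosen contigs (a pair
   counts when both mates align with >= 32 matching bases and <= 2
   mismatches) and greedily fill uncovered reference intervals with reads
   recruited by exact 31-mer seeds and merged by majority consensus.

A bundled simulator (`cpsweep.simdata`) generates circular quadripartite
chloroplast-like genomes (LSC–IRa–SSC–IRb, IRb the exact reverse
complement of IRa), a reference diverged to ~85% identity, and paired
100 bp reads with a 3'-decaying quality profile, so the whole pipeline is
testable offline at desk scale.

## Worked example

Simulate the default 20 kb dataset and run the full pipeline:

```bash
$ cpsweep simulate --seed 7 -o sim
wrote 3000 read pairs, genome 20000 bp, realized identity 0.8529 -> sim

$ cpsweep run -i sim/reads_1.fq -i sim/reads_2.fq -r sim/reference.fa -o out
best configuration: k=61 mrl=17 cutoff=150 coverage 61.69%
```

`out/sweep.tsv` holds one row per configuration:

```
min_read_len  k   hsp_len_cutoff  n_contigs  n_hsps_kept  covered_bp  ref_len  proportion  raw_hsp_bp
17            17  150             28         18           3950        20000    0.197500    3958
17            19  150             33         22           5504        20000    0.275200    5529
...
```

Reading the output: coverage rises from ~20% at k=17 to a peak of 61.69%
at k=61, then collapses toward zero past k≈90 (at depth 30 a k-mer of
length 81 is only covered by ~6 read starts, so high-k graphs fragment) —
the characteristic unimodal curve that makes k the parameter worth
optimising.  The three minimum read lengths give *identical* results on
this dataset because the simulated quality ramp never drops below Phred 13,
mirroring the finding that minimum read length hardly matters.  The
`proportion` column is union coverage and can never exceed 1; `raw_hsp_bp`
is the plain sum of HSP lengths, which double-counts overlaps.

`out/MANIFEST.json` records the seed, all parameters and per-stage
completion, plus the finishing statistics: here 83.23% of read pairs map
back to the chosen contigs, and gap filling raises coverage from 61.69% to
79.13% (`out/gap_report.tsv` lists each gap as closed/partial/open).

The same stages are importable as a library:

```python
from cpsweep import SimParams, simulate_dataset, k_sweep

ds = simulate_dataset(SimParams(seed=7))
table = k_sweep(ds.reads, ds.reference)
print(table.best.k, round(table.best.proportion, 4))   # 61 0.6169
```

## Layout

| module                | role                                                   |
|-----------------------|--------------------------------------------------------|
| `cpsweep.io_formats`  | FASTQ/FASTA/BLAST-tabular readers and writers          |
| `cpsweep.qc`          | Phred truncation and length filtering                  |
| `cpsweep.assembler`   | canonical k-mer counting, unitig extraction, k sweep values |
| `cpsweep.homology`    | seed-and-extend local aligner (x-drop, banded gaps)    |
| `cpsweep.evaluation`  | HSP filters, union coverage, the configuration sweep   |
| `cpsweep.gapfill`     | read-back mapping, gap complement, greedy gap filling  |
| `cpsweep.simdata`     | chloroplast-like genome/read simulator                 |
| `cpsweep.cli`         | `cpsweep` command with per-stage subcommands           |

See `docs/methods.md` for the model, parameter defaults, numerical
choices, and known limitations.
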