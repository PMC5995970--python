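# Methods

This note documents the models and procedures behind `cpsweep`, the
defaults that matter, what the simulator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## The selection statistic

The pipeline treats k-mer length selection as an empirical optimisation.
For each configuration `c = (min_read_len, k, hsp_len_cutoff)` it computes

```
coverage(c) = |U(c)| / L_ref,
U(c) = union of subject intervals of the retained HSPs
```

where the retained HSPs are produced by: assembly at k → contigs ≥ 150 bp →
containment redundancy removal → local alignment to the reference → **best
HSP per query contig** → identity > 85% and length > `hsp_len_cutoff`
(both strictly; "greater than" is taken literally, so identity 85.0 and
length 150 fail).  The best configuration is the argmax of coverage, ties
resolved toward smaller k (smaller k means denser k-mer coverage and a
more conservative assembly).

Summing best-HSP lengths — a common bookkeeping shortcut — double-counts
subject positions hit by more than one contig and can exceed the genome
length.  Coverage here is therefore computed from the interval **union**
(guaranteed ≤ 1), with the raw sum reported alongside (`raw_hsp_bp`) for
comparability with summation-based figures.

Two filter profiles are built in: the sweep profile (identity > 85,
length > cutoff) used for ranking k, and a construction profile
(identity > 80, e-value < 1e-30, length > 150) matching the looser setting
used when the goal is final sequence rather than ranking.

## Quality control

A base with Phred score below 13 (error probability 10^(−13/10) ≈ 0.05)
marks the start of an untrusted 3' segment; the read is truncated from
that base to its end, because removing an interior base would shift the
remainder out of register.  Reads shorter than `min_read_len` after
truncation are deleted ("length less than" is strict, so a read of exactly
the minimum length survives).  Mates are filtered independently and
orphaned mates are kept, flagged unpaired — this retains the maximum
usable sequence; pair-aware filtering is a policy choice the pipeline
deliberately does not impose.

## The internal assembler

A deliberately minimal de Bruijn unitig assembler exists so that the sweep
is runnable and testable without third-party binaries; it is not a
production assembler and external contigs can be supplied instead.

* K-mers are counted canonically (lexicographic minimum of k-mer and
  reverse complement).  Only odd k are allowed: an even-length k-mer can be
  its own reverse complement, which makes canonical counting ambiguous.
* K-mers with count < `min_kmer_count` (default 2) are pruned.  This
  removes singleton error k-mers at typical depths; it is the *only* error
  correction performed.  There is no bubble popping, tip clipping, or
  scaffolding — real assemblers do all three inside their own pipelines.
* Contigs are the maximal non-branching paths of the remaining graph
  (both orientations built explicitly; each contig reported once, in its
  lexicographically smaller orientation).  Isolated simple cycles — e.g. a
  fully covered circular genome — are emitted as a single contig that
  wraps by k−1 bases.
* Determinism: paths are enumerated from the lexicographically smallest
  start node, cycles from their smallest edge, and the final set is sorted
  longest-first.  Assembly output is a pure function of the read multiset.
* `avg_insert_size` (500), `pair_cutoff` (3) and `min_read_contig_align`
  (32) are carried in the configuration for provenance and reused by the
  finishing stages; pair information is *not* used in graph construction.

A structural consequence worth knowing: the two inverted repeats of a
chloroplast genome are exact reverse complements in the truth sequence, so
under canonical k-mers they collapse into a *single* unitig.  Combined
with the best-HSP-per-query rule (which lets that unitig cover only one of
the two IR copies in the reference), unfragmented assemblies cannot exceed
a coverage of about `1 − ir_fraction`.  The uncovered IR copy is exactly
the kind of gap the read-based gap filler can close, which is why post-fill
coverage is the more meaningful end-point.

## The internal aligner

A compact BLASTN-like seed-and-extend procedure, built for interchangeable
HSP production rather than score-identical BLAST emulation (externally
produced 12-column tabular files are the full-fidelity path):

* exact `seed_len`-mer matches (default 19) on both strands seed
  extensions; seeds falling inside an already-extended diagonal are
  skipped;
* ungapped x-drop extension (match +1, mismatch −2, `x_drop` 20) does the
  bulk of the work; the two ends are then polished by a banded
  (half-width 8) affine-gap (−5 open, −2 extend) x-drop extension with
  full traceback, so identities and mismatch/gap counts are exact;
* percent identity is matches / alignment columns (gaps included);
* e-values use Karlin–Altschul `E = K·m·n·exp(−λS)` with the ungapped
  +1/−2 constants λ = 1.28, K = 0.46; they are approximate and serve only
  the optional e-value filter;
* minus-strand hits follow the BLAST tabular convention
  (`s_start > s_end`); all internal interval arithmetic converts once to
  0-based half-open coordinates.

The scoring and heuristic parameters are package defaults, chosen to be
conventional rather than tuned; tests compare the aligner's identities
against a full dynamic-programming local alignment of the same pairs
(tolerance ±3 identity points at 15% divergence).

## Redundancy removal

Overlap-layout merging of contigs is replaced by containment removal: a
contig aligning over ≥ 98% of its own length at ≥ 95% identity (either
strand) to a longer kept contig is dropped, longest-first with ties by
id.  Unitigs from a single graph never contain one another, so this stage
matters mainly for externally supplied or pooled contig sets.

## Finishing

**Read-back mapping.** A read maps when an exact 31-mer shared with a
contig extends (gap-free, on the seed diagonal) to ≥ 32 aligned bases with
≤ 2 mismatches; a pair counts only when both mates map.  The percentage of
pairs used is *truncated* to two decimals, matching the reporting
convention of the worked example the statistic mirrors (988,357 of
2,624,649 pairs → 37.65%).

**Gap filling.** Gaps are the complement of the covered-interval union.
For each gap the left flanking assembled segment is extended rightwards:
reads sharing an exact 31-mer with the current tip are recruited, and each
new column takes the majority base (ties toward higher summed Phred
quality, then alphabetical).  Extension stops at closure (the right
flank's leading 31-mer appears), when no read extends the tip, after
`max_rounds` (50), or when a wander guard (gap length plus two read
lengths) trips.  Closed gaps credit their whole interval; partial
extensions credit the bases added at the left edge; nothing is ever
removed, so post-fill coverage is non-decreasing by construction.  The
procedure is a minimal, testable interpretation of read-based gap
filling, not a reimplementation of any particular finishing tool.

## The simulator

`simdata` emulates the *shape* of a chloroplast resequencing study:

| parameter | default | meaning |
|---|---|---|
| `genome_len` | 20,000 bp | scaled-down plastome (150 kb optional via `--full-size`) |
| `ir_fraction` | 0.15 | each inverted repeat, as a fraction of the genome |
| `ssc_fraction` | 0.14 | small single-copy region (real plastomes: ~12–15%) |
| `divergence` | 0.15 | per-site substitution rate truth → reference (~85% identity) |
| `read_len` / `insert_mean` / `insert_sd` | 100 / 500 / 50 | paired-end geometry |
| `depth` | 30× | pair count = depth·L/(2·read_len) |
| `error_rate_start/end` | 0.001 / 0.02 | linear 5'→3' error ramp |

Fragment starts are uniform on the circle (the genome is doubled during
extraction); insert lengths are normal, resampled into
[2·read_len, genome_len].  Phred scores are computed from the generating
error probability (`round(−10·log10 p)`, capped at 93 when p = 0), so
quality strings are position-deterministic.  Note the default ramp bottoms
out at Phred 17 — above the truncation threshold of 13 — so on default
data QC is an exact no-op and the three minimum read lengths produce
identical sweeps; this is the mechanism behind the "minimum read length
does not matter" result at desk scale.

The 20 kb default keeps the full 126-point sweep under a minute on one
CPU; all sizes in the test suite were chosen for that budget and are
stated in the tests themselves.

What the simulator does **not** model: indel or rearrangement divergence
(substitution-only keeps identity bookkeeping exact), heterogeneous
conservation along the genome (real coding regions are far more conserved
than intergenic spacers — uniform divergence concentrates HSP identities
near the 85% filter threshold, making the strict identity filter much
harsher than on real data), gene content, GC skew, and platform-specific
error profiles.  Passing tests therefore demonstrate the pipeline's
mechanics and its qualitative parameter response (unimodal coverage in k,
insensitivity to minimum read length, recoverable gaps), not real-data
coverage levels.

## Determinism and seeds

All randomness flows through `numpy` generators spawned from one seed
sequence per dataset (separate child streams for genome, divergence and
reads, so each stage is individually reproducible).  The pipeline proper
(QC, assembly, alignment, evaluation, gap filling) is deterministic:
rerunning with the same inputs yields byte-identical sweep tables.

## Known limitations

* The assembler's only cleaning step is count pruning; with the default
  error ramp, coincident sequencing errors (two reads sharing the same
  substitution) survive pruning and fragment unitigs, which depresses
  absolute coverage at every k.  This is intentional scope, not a defect:
  the sweep's *shape* — the quantity of interest — is preserved.
* Best-HSP-per-query caps coverage at ~`1 − ir_fraction` for unfragmented
  assemblies (see above); interpret pre-gap-fill coverage with that
  ceiling in mind.
* The aligner indexes one reference sequence; multi-record references are
  rejected rather than concatenated.
* Gap filling extends left flanks only; a gap at the very start of the
  reference (no left flank) stays open.
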