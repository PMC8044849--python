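# rpqs

Discovery and genomic-context analysis of **repetitive potential
G-quadruplex sequences (rPQS)** in prokaryotic — in particular archaeal —
genomes.

Guanine-rich DNA can fold into four-stranded G-quadruplex (G4)
structures built from stacked G-tetrads. A *potential quadruplex
sequence* (PQS) is here any locus matching the Quadparser-style pattern

```
G{3,5} N{1,5} G{3,5} N{1,5} G{3,5} N{1,5} G{3,5}      (G3-5 L1-5)
```

four G-runs of 3–5 nt separated by loops of 1–5 nt (15–35 nt total).
Most PQS in a genome are composition noise; the interesting signal is
*exact* PQS sequences interspersed many times per genome. `rpqs`
implements that discovery pipeline end to end:

1. **Scanning** (`pqs_scanner`) — lazy non-overlapping matching for
   genome-wide PQS density, and an overlapping mode that keeps only
   *minimal* PQSs (matches containing no shorter match) for repeat
   discovery. Both strands are scanned; minus-strand hits are mapped
   back to forward coordinates.
2. **Null model** (`null_model`) — i.i.d. random sequences at fixed GC
   give the expected density-vs-GC curve (mean ± SD over replicates),
   plus Spearman rank correlation of observed densities against GC.
3. **Repeat discovery** (`repeat_finder`) — minimal PQSs grouped by
   strand-canonical sequence; families with ≥ 4 total occurrences
   (both strands, overlaps counted) are rPQS. Artifact classes —
   homoguanine runs, interspersed GnNiGn (n > 7, i = 1–2) two-run
   repeats, and simple tandem repeats such as (GGGCT)n — are excluded
   from the main table but reported in a side inventory.
4. **Context** (`context_annotator`) — each rPQS copy is placed against
   the CDS annotation: intergenic/genic, flanking-gene orientation
   (head-to-head / tail-to-tail / head-to-tail), distances to the
   facing CDS boundaries, ±100 nt flanks oriented to the G-rich strand,
   and detection of the C-rich 3′ track (minimal motif C₃TC₃) that
   accompanies these repeats, plus optional oriC distance.
5. **Synthetic genomes** (`synthetic_genome`) — annotated genomes with
   planted template copies, C-rich tails, controlled gene layout and a
   machine-readable ground truth, so every stage is testable with exact
   precision/recall and no downloads.

Inputs are FASTA and GFF3; outputs are TSV/BED6/FASTA/JSON.

## Worked example

Generate a 500-kb synthetic genome (GC 0.55) with 12 planted copies of
the default rPQS template plus its C-rich tail, then run the pipeline:

```
$ rpqs synth --out-prefix sim --length 500000 --copies 12 --seed 1
planted 12 copies -> sim.fasta

$ rpqs -v run --fasta sim.fasta --gff sim.gff3 --outdir out
INFO rpqs.cli_report: loaded 1 genome(s) from sim.fasta
INFO rpqs.cli_report: synthetic_1: 12 non-overlapping PQS hits (24.00 per Mb, GC 0.550)
INFO rpqs.cli_report: synthetic_1: 1 repeat families kept, 0 excluded by class
outputs in out
```

`out/repeats.tsv` holds exactly one family — the planted template’s
minimal PQS, reported under its strand-canonical (here C-rich) form
with per-strand counts and every copy position:

```
canonical_sequence    g_rich_sequence       count_forward  count_reverse  total_count
CCCTCCCCTGCCCCCACCC   GGGTGGGGGCAGGGGAGGG   4              8              12
```

`out/context.tsv` classifies each of the 12 copies (all intergenic,
orientation fractions 50% tail-to-tail / 8.3% head-to-head / 41.7%
head-to-tail exactly as planted, every CDS distance 300 nt, C-rich
track with the C₃TC₃ motif at 12/12 copies), and `out/summary.json`
aggregates the same numbers per genome. A density-vs-GC null curve is
produced separately, e.g.
`rpqs null-curve --gc 0.3:0.7:0.1 --length 1000000 --reps 5 --seed 1 --tsv curve.tsv`.

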