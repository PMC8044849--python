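# Methods

## PQS model and scan semantics

A PQS is a match of the pattern `G{r0,r1} L{l0,l1} … G{r0,r1}` with
`n_runs` G-runs (default 4) of `run_min=3`–`run_max=5` guanines and
loops of `loop_min=1`–`loop_max=5` arbitrary bases (15–35 nt at the
defaults). Loops are drawn from `{A,C,G,T}` — deliberately including
G, so a long homoguanine run is itself a formal match; this is why the
artifact classifier exists. Windows containing N never match: N is
absence of information, not a base, so it neither extends a G-run nor
fills a loop.

Two scan modes share one definition of "shortest match at a start
position" (the smallest window starting there that fully matches the
anchored pattern):

* **Non-overlapping (density) mode** — at the leftmost admissible start
  the shortest match is emitted and scanning resumes at its end. This
  reproduces lazy (non-greedy), non-overlapping regex semantics and is
  the hit count used for density.
* **Minimal (repeat-discovery) mode** — the shortest match is generated
  at *every* admissible start, then every interval that properly
  contains another same-strand interval is removed. The survivors are
  the minimal PQSs; they are the atoms of repeat discovery, so that a
  family is identified by its irreducible core rather than by an
  arbitrary extension of it.

Strand handling: the genome is scanned forward and, independently, as
its reverse complement, with minus-strand coordinates mapped back to
the forward strand. We deliberately do not concatenate the genome with
its reverse complement into one string: a junction-spanning match would
be biologically meaningless, and two independent passes give the same
hit set minus such artifacts. Hits overlapping between strands are
both counted; density divides the both-strand hit count by the
single-strand genome length and is reported per Mb.

### Artifact classes

Repeat families whose sequence is a trivial guanine arrangement are not
credible interspersed repeats and are excluded (but inventoried):

* `homopolymer` — entirely G.
* `two_run_long_g` — exactly two maximal G-runs, each **longer than
  7 nt**, separated by 1–2 non-G nt (the interspersed GnNiGn family).
  Because the minimal match inside e.g. G8-TA-G8 trims the terminal
  runs to 7 G, classification first extends the match's terminal
  G-runs to their maximal genomic extent; without this extension the
  class is undetectable from the match sequence alone.
* `tandem_simple_repeat` — our operationalization of "simple regular
  repeat": some period p ≤ 6 matches at ≥ 90 % of comparable positions
  (`seq[i] == seq[i-p]`). This captures (GGGCT)n, (GGGAA)n, (GGGCGA)n
  and similar; the canonical single-base-loop PQS (GGGA)₃GGG is also —
  correctly — a period-4 tandem. Precedence: homopolymer >
  two_run_long_g > tandem.

## Repeat discovery

Minimal PQSs are grouped by strand-canonical sequence (lexicographic
minimum of the sequence and its reverse complement; idempotent and
strand-invariant). A family's copy number is the count of *raw
substring occurrences* of its G-rich representative plus its reverse
complement on the forward strand, overlaps included — a planted motif
is present wherever its exact sequence occurs, whether or not the
minimal-match machinery reports a locus there (inside a poly-G run,
occurrences tile densely; that is the honest count under this
definition, and the family is excluded as homopolymer anyway).
Families with total count ≥ `min_copies` (default 4) are rPQS.
Grouping is by exact sequence identity only: loop variants of a family
(e.g. GCA- vs ACC-loop versions) appear as separate rows, with no
fuzzy clustering. The cross-genome table fills every cell by direct
occurrence counting, including in genomes where the row is not itself
an rPQS.

## Gene context

Placement uses the match midpoint against CDS intervals,
strand-agnostically — the flanking-gene statistics are defined
irrespective of which strand carries the G-rich sequence, which is
instead reported separately (sense/antisense fractions). The nearest
CDS ending before the midpoint is the left gene, the nearest starting
after it the right gene; on circular replicons the search wraps, on
linear ones a missing neighbor yields an `unpaired` record. Orientation
of the pair follows the standard prokaryotic convention from the two
strands alone: (+,−) tail-to-tail, (−,+) head-to-head, equal strands
head-to-tail.

Distances are measured from the match boundary nearest the gene to the
gene's *facing* boundary, labelled as that gene's CDS start (5′ end on
its own strand) or CDS end (3′ end); overlap gives distance 0 with a
flag. Measuring from the boundary rather than the midpoint is a
documented choice; the midpoint alternative shifts every value by half
a match length and does not change orientation statistics.

Flanks of `window` nt (default 100) are read 5′→3′ on the G-rich
strand, so the 3′ flank of a minus-strand copy is the reverse
complement of the genomic sequence upstream of the match. The C-rich
track detector searches the first 30 nt of the 3′ flank for the
leftmost maximal `C{3,} X C{3,}` segment (X any single base) and flags
the minimal C₃TC₃-family motif when X = T; the reported C fraction is
the maximum over 12-nt windows in the search region (for the reference
tail `GCCCCCTCCCCGCA` this is 10/12, from the window starting at
offset 1). Detection is deterministic by design — the package detects
the known motif rather than re-running de novo motif discovery, and
exports flank FASTA for external discovery tools.

## Null model

Random sequences are i.i.d. with p(G) = p(C) = GC/2 and
p(A) = p(T) = (1−GC)/2 — the maximum-entropy composition consistent
with a GC fraction. The density curve takes `n_replicates` (default 5)
independent sequences per GC grid point and reports mean and sample SD
(ddof = 1). Replicate streams derive from
`SeedSequence(base_seed, spawn_key=(grid_index, replicate_index))`,
which is deterministic, collision-free across the grid, and stable
across platforms for a fixed numpy generation. Reference scale is
10 Mb per replicate; 1 Mb (the default, used by the acceptance script)
already separates neighboring grid points far outside replicate SD for
GC ≥ 0.4 and keeps the computation in seconds. Spearman correlation
(average-rank ties, large-sample t approximation for p) is delegated
to scipy with input validation; a constant vector raises rather than
returning NaN. Dinucleotide- or Markov-preserving shuffles would be a
natural extension; they are intentionally out of scope.

## Synthetic genomes and what they do (not) show

The generator plants `n_copies` (default 12) of a template — by
default the GCA-loop rPQS core `CTGGGGGGTGGGGGCAGGGGAGGGGGCTC` with
its natural 3′ tail `GCCCCCTCCCCGCA` — into an i.i.d. background
(default 500 kb, GC 0.55, circular). Each copy gets its own CDS pair
(default 600 nt, CDS-only gene model) whose strands realize the site's
orientation class, placed so that the gap between the *PQS match*
boundary and each CDS is exactly the spacer (default 300 nt).
Orientation quotas default to 50 % tail-to-tail, 11 % head-to-head,
39 % head-to-tail, resolved by largest remainder (6/1/5 at 12 copies)
and shuffled positionally; strands are drawn per copy from
`strand_mix` (default 0.5). Templates are validated at construction to
contain exactly one minimal PQS and no reverse-strand match, which is
what makes ground-truth coordinates well defined.

In scrub mode (default), background windows that accidentally match
the pattern on either strand are re-rolled (planted positions are
protected) until the planted matches are the only minimal PQSs, with a
bounded retry loop (100 rounds; a match lying entirely inside a
protected insert is an error, as it would indicate a self-conflicting
template). Scrubbing makes recovery checks exact: precision, recall,
strand accuracy, orientation confusion and C-track detection are all
expected to be 1.0, and the tests assert exactly that.

Passing these checks demonstrates correctness of the machinery —
coordinate bookkeeping, strand mapping, grouping, counting,
classification — under a controlled model. It does **not** demonstrate
performance on real genomes: the background is compositionally i.i.d.
(no codon structure, no GC skew, no operons), gene lengths are fixed,
copies of a family are identical rather than loop-variant, and real
annotations contain nested and overlapping features the generator never
produces. Generation is byte-deterministic given the spec and seed.

## Numerical and interface choices

* Internal coordinates 0-based half-open; GFF3 1-based inclusive at the
  file boundary; BED6 0-based half-open. One conversion layer, exact
  bijection.
* Circularity comes from a flag or the GFF3 region feature's
  `Is_circular` attribute; default linear.
* All TSV floats are written with a fixed format (`%.6f`), making
  outputs byte-reproducible for identical inputs and seeds.
* Tie-breaks are total and documented: matches sort by (start, strand,
  end) with '−' after '+'; repeat families by (descending total count,
  canonical sequence); genes by (start, end, locus_tag).
* Degenerate inputs fail loudly: empty FASTA, '.' strands, coordinates
  outside a declared sequence-region, all-N sequences (undefined GC),
  constant vectors in the correlation, infeasible synthetic packings.

## Known limitations

* Occurrence counting is exact-match only; a single substitution
  splits a family. This is intentional (it mirrors the definition of
  an exact interspersed repeat) but means copy numbers are a lower
  bound under sequencing error.
* The ≥ 4-copy threshold counts occurrences, not minimal-match loci;
  for self-overlapping sequences these differ. The choice is
  documented above; the locus-based alternative can be recovered from
  the reported copy positions.
* Scoring-based G4 predictors (G4Hunter-style), RNA G4s and
  bulged/imperfect quadruplex models are out of scope.
* Each FASTA record is treated as an independent replicon and
  aggregated per assembly; plasmid-aware weighting is left to the
  caller.
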