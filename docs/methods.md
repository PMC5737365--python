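# Methods

`svrecur` validates predicted structural variants (SVs) by asking, read by
read, whether the local long-read evidence matches the reference as it is or
the reference as the prediction says it should be. This note documents the
model, the tunable parameters, the synthetic data the package evaluates
itself on, and the numerical choices made where the procedure left room.

## Reference pair construction

Every SV is materialised as a pair of windows: the original reference
`R_o = [start - flank, end + flank)` and the altered `R_a`, identical in
both flanks, with the interior rewritten by the predicted rearrangement.
All rearrangements, built-in and complex, reduce to an ordered list of
*pieces* — reference intervals, possibly reverse-complemented, plus literal
inserted sequence — produced by a segment-recipe grammar (deletion = empty
recipe, inversion = `a^`, tandem duplication = `a a`, inverted duplication
= `a a^`, deletion-inversion = `b^` over two half-segments,
deletion-duplication = `b b`). Boundaries between pieces that are not
forward-colinear in the reference are *novel junctions*; each junction keeps
its reference anchor coordinate, its position in the altered string, and a
flag describing how to locate the corresponding query position on a read
(before or after inserted bases at the anchor). Coordinates are 0-based
half-open everywhere inside the package; converters live only at the VCF and
BED parsers.

`flank_len` defaults to 800 bp. Breakpoint-offset robustness scales with
the flank, and 800 bp comfortably exceeds the ~200 bp robustness radius the
offset-scan reproduces while keeping windows (and runtime) small.

## Recurrence matrices

The dot plot of a read segment against a window records `(x, y)` whenever
the k-mer at read offset `x` exactly equals the window k-mer at `y` (1-bp
step, hash lookup; an all-pairs loop is kept in the test suite as the
independent oracle). k-mers containing N never match. Reverse-complement
matches are recorded in a separate channel and included in all scores: a
balanced rearrangement such as an inversion produces *absence* of forward
matches rather than displaced ones, and only the anti-diagonal RC matches
against the mismatching reference give the distance statistics something to
penalise. Forward-only matching is available (`include_rc=False`) but
cannot discriminate inversions.

### Window-size quality control

Repetitive windows flood the matrix with spurious matches. Before scoring,
the original window is compared against itself with k growing from 10 bp in
10-bp steps; the first k at which the diagonal holds strictly more than 40%
of all self-match records is used for scoring. If 40 bp still fails, the
event is `NONASSESSABLE` and excluded (counted separately from sensitivity).
On the i.i.d. synthetic genomes below this essentially never triggers; it
exists for real repeat-rich references and for degenerate inputs
(homopolymer stretches fail as they should).

## Per-read scores

**Small events** (more than `min_span_reads = 10` primary reads whose
footprint covers `[start - 50, end + 50]`): the read segment aligned across
the whole window is extracted via the CIGAR, and each matrix is summarised
by the mean vertical distance to the diagonal, `sum|x - y| / m`. When the
altered allele contains a duplicated segment the directed form
`|sum(x - y)| / m` is used for both matrices instead, so the centrosymmetric
record pairs that a genuine duplication produces cancel rather than
penalise. The normalized read score is `S_o / (S_a + 0.5) - 1`; the 0.5
pseudocount keeps a read identical to one reference (distance 0) finite
without affecting sign or ordering.

**Large events** (too big for enough fully spanning reads): each read
anchored across a junction contributes one score per junction. The segment
±`junction_flank` (400 bp) around the junction's query position is scored
against the *full* `R_o` and `R_a` windows with coordinates expressed in
each window's frame, junction aligned to junction, using the match fraction
`#{|x - y| < 0.15 x} / m`. Scoring against full windows matters: content
from the wrong side of a junction still finds its k-mer matches, but far
from the diagonal, where the relative tolerance rejects them and they dilute
the score of the reference lacking the predicted structure. Both fractions
share the larger of the two record counts as denominator, so novel inserted
sequence — which has no matches against `R_o` at all — lowers the original
reference's score instead of silently vanishing. Normalization is inverted
(`S_a / (S_o + eps) - 1`, guard `eps = 1 / (max(m_o, m_a) + 1)` on the
match-fraction scale).

### Read-coordinate expansion correction

Long-read error profiles are insertion-dominated; with 15% total error split
5:75:20 among substitutions:insertions:deletions, read coordinates advance
~8% faster than reference coordinates. Left uncorrected, this deterministic
slope dominates `|x - y|` for small events and destroys the directed
statistic's cancellation. The validator therefore estimates a single global
expansion factor γ — the median of (aligned query length / reference span)
over 300 sampled primary reads — and multiplies read coordinates by `1/γ`,
anchored at each segment's extraction point. The correction is
alignment-observable and SV-independent; residual noise is the per-read
random walk (~tens of bp over a window), far below typical SV signals.

## Aggregation and genotype

The validation score of an SV is the fraction of scored reads with strictly
positive normalized score (`> 0`; exact zeros count as non-supporting), with
the maximum read score reported alongside. Reads with empty matrices
against both references are dropped from the denominator. At most 100 reads
per SV are used, chosen deterministically by MD5 of the read name, so
reruns are byte-identical at any depth. Recommended reporting cutoffs are
0.15 on the validation score and 0.1 on the max read score; both are emitted
as boolean columns, never applied as hard filters.

Genotypes use the biallelic read-support log-likelihood with `j` of `k`
reads non-positive and per-read error rate ε (default 0.05, re-estimable
from truth-labelled homozygous sites via `estimate_error_rate`). `g` counts
reference alleles (`g=0 → 1/1`, `g=1 → 0/1`, `g=2 → 0/0`); this orientation
is forced by the formula itself — enumeration shows the likelihood peaks at
`g=0` when every read supports the event — and is isolated in one mapping
table. Genotype quality is the log10 gap between the best and second-best
genotype; ties give 0. Log arguments are floored at 1e-12 so degenerate ε
stays finite.

## Synthetic data generator

The simulator emulates the published evaluation design at desk scale:

| parameter | default | meaning |
|---|---|---|
| `genome_len` | 5 Mb | i.i.d. random reference (GC 0.5) |
| `n_svs` | 50 per class, 7 classes | non-overlapping, ≥5 kb apart, ≥20 kb from contig ends |
| `sv_len` | 100 bp – 5 kb | log-uniform |
| zygosity | alternating het/hom | het on haplotype 1 only |
| `depth` | ×20 | total diploid coverage, split evenly across haplotypes |
| `read_len_mean` | 12,000 bp | log-normal, σ(log) = 0.3, floor 500 bp |
| `accuracy_mean` | 0.85 | per-base error 0.15 |
| `diff_ratio` | 5:75:20 | substitution : insertion : deletion share of the error budget |

Reads are placed uniformly on each haplotype and their alignments are
derived from the simulation truth through the haplotype→reference liftover
instead of running an aligner; this keeps the loop hermetic, deterministic
and dependency-free, and any externally aligned BAM can be supplied to the
validator instead. Error-induced indels are aggregated into the CIGAR per
250-bp source block (`M(min) + I/D(diff)` per block), bounding coordinate
anchoring error by ~±25 bp — well inside the scoring tolerances — while
keeping CIGARs short. Reads lying entirely inside novel insertions are
parked at the insertion point almost fully soft-clipped. Deliberately false
calls are made by relocating every truth SV to a random locus ≥2 kb clear of
any real variant, mirroring the false-validation device of assessing calls
at coordinates where the reads carry no rearrangement.

What the generator does **not** emulate, and hence what passing tests do not
show: real genomes are not i.i.d. — segmental duplications and tandem
repeats will push more windows into larger k-mers or `NONASSESSABLE`, and
mapping artefacts near real SVs are absent here because placements come from
truth. Per-read accuracy is constant (no quality model), there are no
chimeric reads, and the substitution matrix is uniform. Sensitivity/FDR
measured on this generator characterise the scoring machinery under the
stated error profile, not caller performance on real data.

## Numerical and design choices

- Strict `>` at the 40% diagonal threshold and at the score-positivity and
  cutoff comparisons; record `(0, 0)` never passes the junction tolerance
  (`|0 - 0| < 0.15·0` is false).
- A read with matches against exactly one reference gets the maximal
  distance (window length) on the empty side in small mode, and match
  fraction 0 in junction mode.
- Deletion-duplications built from equal halves change the window length by
  ≤1 bp; the directed-distance signal is then O(1) per record, so
  individual reads can flip sign on spurious k-mer repeats even with perfect
  reads. Aggregate sensitivity stays high, but per-read antisymmetry and
  genotype concordance are intrinsically weaker for this class — genotype
  concordance under noise is therefore quoted for deletions and inversions,
  where the evidence model matches the data.
- In junction mode, reads whose aligned span crosses a duplication's
  reference anchor but whose content lies entirely inside the duplicated
  copy are genuinely allele-ambiguous; they dilute homozygous duplication
  scores toward ~0.5–0.7, which still validates at cutoff 0.15 but can
  shift the genotype toward het.
- Benchmark conventions: sensitivity is computed over assessable true
  events (QC failures are reported as a separate pass rate, not counted as
  misses); FDR is validated-false / all-validated.

## Problem sizes used in the shipped evaluation

The acceptance script and the heavyweight tests run the 5-Mb / 350-SV / ×20
study (plus a ×10 rerun for the insertion/deletion QC census and a 400-kb
×30 fixture for breakpoint-offset robustness). These sizes give ≥50 events
per SV class and finish in a few minutes on one core; metrics were stable
across seeds at this scale in development.
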