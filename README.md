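# svrecur

Recurrence (dot-plot) validation of predicted structural variants from
long-read alignments.

Structural-variant (SV) callers working from short reads produce candidate
deletions, insertions, duplications, inversions and complex rearrangements
whose truth status is hard to establish without manual dot-plot curation.
`svrecur` automates that curation: for every predicted SV it compares the
long reads spanning the locus against two local reference sequences — the
original window `R_o` and an altered window `R_a` that carries the predicted
rearrangement — and reports the fraction of reads that fit the altered
structure better, together with a likelihood-based diploid genotype.

## The score

For a read and a reference window, a recurrence matrix records every pair
`(x, y)` where the k-mer at read position `x` equals the reference k-mer at
position `y` (1-bp step, exact match; reverse-complement matches are kept in
a separate channel so inversions leave an anti-diagonal signature against
the unmodified reference). With `m` matrix records, events small enough to
be fully encompassed by more than 10 reads are scored by the mean distance
to the diagonal,

    Score_Rx = (1/m) * sum_i |x_i - y_i| ,

replaced by the duplication-corrected directed form
`|sum_i (x_i - y_i)| / m` whenever the altered allele repeats a reference
segment. The per-read normalized score is

    Score_R = Score_Ro / Score_Ra - 1 ,

positive when the read matches the predicted structure better. Events too
large to be spanned are assessed per junction with a relative-tolerance
match fraction (`|x - y| < 0.15 x`) and the inverted normalization
`Score_Ra / Score_Ro - 1`. The per-SV **validation score** is the fraction
of reads with a positive normalized score (recommended reporting cutoff
0.15; the best single-read score is also reported, cutoff 0.1).

Repetitive windows are caught before scoring by comparing the reference
window against itself: the k-mer size grows 10 → 40 bp in 10-bp steps until
more than 40% of self-matches lie on the diagonal, and regions that never
get there are reported `NONASSESSABLE`.

Genotypes come from the standard biallelic read-support likelihood with `j`
of `k` reads non-supporting and per-read error rate ε (default 0.05),

    l_g = -k log 2 + sum_{i<=j} log((2-g)ε + g(1-ε))
                   + sum_{i>j}  log((2-g)(1-ε) + gε) ,

where `g` counts reference alleles; the call is the argmax and the genotype
quality is the gap to the runner-up in -log10 units.

## Worked example

Simulate a small study (synthetic 300-kb genome, one SV of each class in
het/hom states, noisy 12-kb reads at ×20) and validate the truth set plus
deliberately false calls:

```bash
svrecur simulate --out-dir demo --genome-len 300000 --depth 20 \
    --n-per-type 1 --seed 5
svrecur validate --genome demo/genome.fa --bam demo/reads.bam \
    --svs demo/truth.tsv --out-dir demo/out
```

which prints (output of this exact command):

```
Structural-variant validation summary
======================================
events evaluated        7
  PASS                  7
validated (score>0.15)   7 / 7
mean validation score   0.667
mean reads per event    19.9
```

`demo/out/svrecur_results.tsv` holds one row per SV (columns abridged):

```
chrom  start   end     svtype      id       n_reads  mode   vapor_score  max_read_score  genotype  qc_flag
chrS   43220   43930   DEL_DUP     sim0002  14       SMALL  0.5000       7.3394          0/1       PASS
chrS   177169  177358  INV         sim0006  19       SMALL  0.4211       0.9598          0/1       PASS
chrS   214852  214852  INS         sim0004  25       SMALL  0.3600       28.8733         0/1       PASS
chrS   249463  251180  DUP_TANDEM  sim0005  17       SMALL  1.0000       120.7977        1/1       PASS
chrS   273132  273511  DEL         sim0001  23       SMALL  1.0000       31.1024         1/1       PASS
```

A `vapor_score` of 0.36 with genotype `0/1` means 36% of the 25 spanning
reads fit the predicted insertion better than the reference — the expected
signature of a heterozygous event — while homozygous events score 1.0 and a
relocated false call shows `vapor_score` 0 and genotype `0/0`. The same
objects are available as a library:

```python
from svrecur import SVValidator
results = SVValidator("demo/genome.fa", "demo/reads.bam", "demo/truth.tsv").fit()
print(results.summary())
table = results.table            # pandas DataFrame, one row per SV
```

`svrecur benchmark` compares a results table with a truth set (sensitivity,
FDR, QC pass rate, cutoff sweep), and `svrecur offset-scan` re-assesses SVs
with breakpoints shifted by a grid of offsets to map breakpoint robustness
or refine uncertain calls. With VCF input, `svrecur validate --annotate-vcf`
also writes a copy of the VCF carrying `VAPOR_SCORE`, `VAPOR_GT` and
`VAPOR_QC` INFO keys; `--config file.yaml` supplies any `RunConfig` field
from a file, with command-line flags taking precedence.

## Complex rearrangements: the recipe grammar

Complex classes are expressed as an ordered recipe over lettered
sub-segments of the SV interval (`a`, `b`, ... tile `[start, end)`; `^`
means reverse complement; letters may repeat or be omitted). The built-in
classes are canonical recipes — tandem duplication `a a`, inversion `a^`,
inverted duplication `a a^` — and BED-like input can supply its own:

* deletion-inversion (`DEL_INV`): segments `a b`, recipe `b^` — the left
  half is deleted and the right half inverted:
  `chrS  1000  1800  DEL_INV  cx1`
* deletion-duplication (`DEL_DUP`): segments `a b`, recipe `b b` — the left
  half is deleted and the right half duplicated:
  `chrS  1000  1800  DEL_DUP  cx2`
* custom, with explicit breakpoints:
  `chrS  1000  1900  CUSTOM  cx3  RECIPE=a,c^;SEGS=1000,1300,1600,1900`

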