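# seqsift

Index-free, alignment-based filtering of records on the command line.

`grep` answers "which records contain this exact pattern?"; bioinformatics
pipelines usually need "which records *approximately* contain this query?" —
tolerant of substitutions and indels, aware of record structure (a FASTA
record is a header plus a possibly wrapped sequence, not a line), and
composable in a shell pipeline without building an index first. `seqsift` is
a Unix-style stream filter for exactly that: it aligns a query against every
FASTA, FASTQ, or plain-line record it reads, and passes through — unmodified,
in input order — only the records whose alignment score clears a threshold.

It is aimed at people who live in shell pipelines: checking pipeline outputs
for a splice junction or adapter, pulling reads that carry a known motif,
or fuzzy-searching a codebase where capitalization and typos get in the way.

## The method

For query *q* (length *m*) and record sequence *t* (length *n*), seqsift
computes an affine-gap dynamic-programming alignment score, either

- **local** (Smith–Waterman–Gotoh): best-scoring subsequence pair, scores
  floored at zero, or
- **semi-global**: full-matrix DP in which any combination of the four
  sequence ends (query/target × prefix/suffix) may be declared "free"
  (unpenalized). All ends penalized is global (Needleman–Wunsch) alignment;
  the default frees both target ends, i.e. the whole query must align while
  target overhangs cost nothing.

A gap of length ℓ costs `gap_open + (ℓ − 1) · gap_extend` (defaults 3 and 1).
Three substitution schemes are built in: **ACTGN** (match +2, mismatch −2,
N scores 0 against everything), **BLOSUM62** (standard 24-symbol table) and
**ASCII** (uniform ±2 over case-folded bytes, for general text).

A record passes the filter when

```
score(q, t)  ≥  τ · optimal(q),      optimal(q) = Σᵢ S(qᵢ, qᵢ)
```

where `optimal(q)` is the query's gapless self-alignment score and τ is the
threshold (default 0.8). The comparison is made in exact rational
arithmetic, so boundary cases are decided by ≥, never by float rounding.

The inner loop is the striped (Farrar) vectorized DP refined by SSW, over an
abstract lane axis: lane-striped query profiles, a lazy-F correction loop,
and adaptive precision — local alignment starts in biased, saturating
unsigned 8-bit arithmetic and transparently reruns in 16 bits when the score
saturates. Semi-global scoring is signed 16-bit only (without the local zero
floor, signed 8-bit overflows almost immediately). Every striped result is
bit-identical to the scalar DP oracle, for every lane count.

## Worked example

Search a compressed FASTA file for a 31-nt query at threshold 0.8:

```sh
$ seqsift CACTTGGGCCTCAGCTTTCAGAGCCCTCGGG \
    --scoring-matrix actgn \
    --record-type fastx \
    --threshold 0.8 \
    reads.fa.gz
>contig1
CGGACTCTGGGCACTTGGGCCTCAGCAAACAGAGCCCTCGGGAGGATCCGGCT
```

The contig embeds a copy of the query with 3 substitutions at bytes
[11, 42): the best semi-global score is 28·2 − 3·2 = 50 against an optimal
of 31·2 = 62, a normalized score of 50/62 ≈ 0.806 ≥ 0.8, so the record is
emitted (at `--threshold 0.9` it would not be). On a terminal the matched
span is shown in inverse video; in a pipeline, as above, the record is
byte-identical to its input form. Exit codes follow grep: 0 with ≥ 1 match,
1 with none, 2 on error.

Line-mode search of a source tree (recursive, skipping dotfiles and binary
files; ASCII scoring tolerates case and small typos):

```sh
$ seqsift simd_widthof ./src
```

The same machinery is available as a library: `build_scheme`,
`local_adaptive` / `semiglobal_striped`, `filter_stream`, and the
`fixtures` module for generating seeded synthetic corpora with
oracle-computed ground truth.

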