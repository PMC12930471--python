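# Methods

## Alignment model

All scoring is affine-gap Gotoh dynamic programming with three state
matrices H (match/mismatch), E (gap in the query, i.e. consuming target)
and F (gap in the target, consuming query):

```
E[i][j] = max(H[i][j−1] − Go,  E[i][j−1] − Ge)
F[i][j] = max(H[i−1][j] − Go,  F[i−1][j] − Ge)
H[i][j] = max(H[i−1][j−1] + S(qᵢ, tⱼ),  E[i][j],  F[i][j])      (+ floor 0 in local mode)
```

so a gap of length ℓ costs `Go + (ℓ−1)·Ge`. Defaults Go = 3, Ge = 1.

**Semi-global boundaries.** Row/column 0 encode the prefix flags:
`H[i][0] = 0` when the query prefix is free, else `−(Go + (i−1)·Ge)`, and
symmetrically for `H[0][j]` with the target prefix. The final score is the
maximum over the cell set selected by the suffix flags: the bottom-right
cell when both suffixes are penalized, plus the last row when the target
suffix is free, plus the last column when the query suffix is free. The
boundary cells of those vectors (i = 0 / j = 0) are included as degenerate
candidates; this is symmetric, deterministic, and only ever surfaces when
every real alignment scores worse. With all four ends penalized the model
reduces to global (Needleman–Wunsch) alignment, which is tested against an
independent textbook implementation.

**Tie-breaking.** Among equal-scoring end cells the smallest target end
wins, then the smallest query end. One shared reduction helper is used by
the scalar and striped paths, so their results are identical including ties;
this is also what makes results independent of lane count.

**Optimal score.** The filter normalizes by the query's *gapless*
self-alignment score Σᵢ S(qᵢ, qᵢ). Gap penalties do not enter the
denominator: an optimal self-alignment never opens a gap when every
diagonal entry is its row maximum, which holds for every symbol in the
ACTGN and ASCII schemes and for all BLOSUM62 symbols except X (whose
published self-score, −1, is below its 0 against S/T/A; queries of standard
residues are unaffected). A query with non-positive self-score (e.g. all N)
cannot be normalized; the encoder warns and the filter refuses it.

## Striped kernels

The striped layout places query position `k = lane·segLen + i` at segment
position `i` of lane `lane`, with `segLen = ⌈m/L⌉`; padding positions carry
the neutral score (0 raw, the bias in the 8-bit profile) and are masked out
of maxima. Per target position the kernel computes H from the lane-shifted
diagonal plus profile scores, folds in E and F, then runs the lazy-F loop —
shift F across lanes and re-relax until no element satisfies
`F > H − Go` — which is bounded by `segLen · L` iterations per column (the
bound is asserted in tests). E for a column is derived in one vector
operation from the *corrected* previous column, so lazy-F fix-ups can never
leave stale E values behind.

Three deliberate departures from a hardware SIMD implementation:

- **Lanes are an abstract numpy axis.** Any power of two ≥ 2 works
  (default 16, overridable by `--lanes` or `SEQSIFT_LANES`); the algorithm
  (striping, lazy-F, saturation, bias) is what is preserved, not intrinsics.
- **8-bit saturation is emulated** by clipping inside wider integers:
  values carry +bias (bias = −min S), adds clip at 255, subtracts floor
  at 0. A run is flagged overflowed when the biased maximum reaches
  `255 − max(profile)` — conservative: any cell that actually clipped is at
  or above this line, so an unflagged result is provably exact.
- **16-bit precision is emulated in int32 with an a-priori guard**: inputs
  whose score range could reach ±32767 (bounded via `min(m,n)·max(S)` and
  the worst boundary-gap magnitude) raise an overflow error up front
  instead of wrapping. This keeps the adaptive path's third-tier failure
  cheap, explicit and exact.

`local_adaptive` runs u8 first and reruns at 16 bits only on saturation;
`semiglobal_striped` is 16-bit only and rejects a u8 request with a
configuration error.

## Filtering

The threshold is stored as an exact `fractions.Fraction` (CLI strings like
`0.8` parse to 4/5) and the decision is the cross-multiplied integer test
`raw · den ≥ num · optimal`, so a record sitting exactly on the boundary is
emitted — the rule is ≥. Matched spans are recovered by rerunning the
scalar DP on the prefix rectangle ending at the reported cell and walking
H/E/F back (preference diagonal → E → F; the span score is tie-invariant).
With multiple threads, records are evaluated concurrently and re-sequenced
to input order, so output is byte-identical for any thread count.

## Synthetic corpora

The fixtures generator emulates the filter's target regime: records that
embed a copy of the query carrying independent per-position substitutions
(forced to differ) and indels, between random flanks, mixed with pure
random records of comparable length. For every record it logs the scalar
oracle score, so the exact expected output at any threshold is computable
in advance. Defaults used by the end-to-end tests: 500 records, half
planted, substitution rate 0.08 and indel rates 0.02 — a moderate mutation
load that spreads normalized scores across the 0.5–1.0 threshold range
rather than clustering at either extreme. All randomness flows through
`numpy.random.default_rng` (PCG64) with explicit seeds, so corpora are
byte-stable across platforms.

What the generator does *not* emulate: realistic sequencing error profiles
(position-dependent error, homopolymer artifacts), quality strings (a
constant placeholder is used), or correlated/structured variation. Passing
tests therefore demonstrate algorithmic correctness of the scoring,
thresholding and stream plumbing on controlled inputs — not calibration of
thresholds for any particular instrument's error process.

## Problem sizes and numerical choices

Randomized equivalence suites use 1000 pairs per mode at lengths 1–200
across all three schemes and sampled end-flag combinations, 200-pair
lane-invariance and global-reduction sweeps, and a 500-record end-to-end
corpus — sizes at which the full-matrix oracles remain exact and fast while
still exercising multi-segment striping, saturation and re-sequencing.
Internal sentinel for −∞ is −2²⁸, far enough from int32 limits that no
subtraction can wrap. Directory traversal is lexicographic and binary
detection is "NUL byte in the first 8 KiB", both for deterministic,
grep-like behavior; explicitly named files bypass the dotfile/binary skips.

## Known limitations

- One best span per record; no suboptimal or multiple matches, no CIGAR.
- No E-values or bit scores — the normalized-score threshold is the only
  decision rule.
- FASTQ is the 4-line dialect only; qualities are carried through but never
  aligned against.
- No user-supplied matrices and no IUPAC ambiguity codes beyond N.
- The GCUPS benchmark subcommand measures this implementation on the host
  at hand; numpy-over-lanes throughput is not comparable to hardware SIMD.
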