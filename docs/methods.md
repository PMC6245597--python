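# Methods

## Model

The engine computes the optimal local alignment score of two DNA sequences
under the affine-gap Smith-Waterman model (Gotoh's three-matrix recurrence).
H[i,j] is the best score of any local alignment ending at (i, j); E and F
carry the best scores of alignments ending in a gap in S1 or S2
respectively. A gap of length k costs Go + k·Ge with Go, Ge ≥ 0 stored as
magnitudes and subtracted by the recurrences. The optimum is max H, and only
the score (plus its position) is produced — there is no traceback and no
alignment reconstruction, which keeps memory independent of n.

Boundary convention: H, E and F are all taken as 0 at i = 0 and j = 0
(literally, not −∞). This admits spurious "gap from the border" chains in
E/F, but those chains start at ≤ −Ge and only decrease, so they never reach
a nonnegative value and cannot affect H; the convention is applied
identically in the oracle and the blocked engine, so the two are bit-equal.
A corollary used by the tests: every interior E and F value is ≥ −(Go+Ge),
which also bounds the dynamic range any integer width must represent.

## Blocked computation

The H matrix is divided into ⌈n/BW⌉ vertical blocks of BW columns. Each
block is swept row by row, top to bottom and left to right, holding one H
row and one F row of length BW (F propagates only vertically, so it needs
no inter-block state). What crosses a block seam is the last-column H and E
vector of the previous block, length m, kept in a read/write buffer pair
swapped after every block; an all-zero pair encodes the j = 0 column. The
target is padded with a reserved non-ACGT residue (`X`) to a multiple of
BW.

Substitution rule: match iff both residues are equal and in {A,C,G,T};
every non-ACGT residue — N, IUPAC ambiguity codes, the pad symbol — scores
`mismatch` against everything, itself included. This is conservative and
deterministic, and it makes padding provably inert: every pad-column cell's
value traces back to a real cell that is reached earlier in row-major order
and is at least as large, so neither the score nor the reported position
can move into a pad column. The engine enforces mismatch < 0 whenever
padding is actually required, since a nonnegative mismatch would break that
argument.

Tie-breaking: the reported (max_i, max_j) is the first maximal cell in
row-major order (smallest i, then smallest j) over the unpadded matrix,
1-based. When the score is 0 no positive cell exists and (0, 0) is
reported. Within a block the scan order is already row-major; across
blocks, a block to the right can win a tie only with a strictly smaller
row index.

## Integer-width guard

Scores may not exceed min(m,n)·match (match > 0 is required), so
admissibility at a width is decided a priori by comparing that bound with
the width's maximum value (127 / 32767 / 2147483647). Inadmissible runs are
refused with the minimum admissible width named, rather than saturating or
wrapping per cell; arithmetic itself is carried out in 64-bit integers, the
guard guaranteeing that all values also fit the emulated width. This keeps
the inner loop branch-free and makes results at any two admissible widths
identical by construction (checked by tests anyway).

## Parameters

- `match` (+1), `mismatch` (−3), `gap_open` (5), `gap_extend` (2): the
  conventional DNA scoring used throughout; all integer, penalties as
  positive magnitudes.
- `block_width` (default 512): columns per block. In software it trades
  boundary-buffer traffic against row-buffer locality and has no effect on
  results; 512 keeps both buffers comfortably in L1/L2 for megabase
  sequences.
- `int_width` (default 32): emulated score width; 8 or 16 are useful to
  model narrow-arithmetic deployments and are guarded as above.
- `repetitions` (bench, default 10): timed runs averaged into the reported
  mean runtime and GCUPS.

Runtime accounting: `runtime_s` covers buffer setup, the blocked sweep and
score retrieval; FASTA parsing is excluded. GCUPS = m·n / (t·10⁹) with the
unpadded lengths.

## Synthetic data

`swblock.synth` generates a uniform i.i.d. ACGT sequence and mutates it in
a single per-position pass: deletion with p_del, else substitution to a
uniformly chosen *different* base with p_sub, and after every original
position a single uniform-base insertion with p_ins (rates must sum to
≤ 1; everything is deterministic under the model seed, with the mutation
stream keyed separately from the base-sequence stream so the two are
independent). Sweeping p_sub from 0 to 1 spans near-identical to
essentially unrelated pairs, which is the axis the engine must be
insensitive to.

This is deliberately not a genome simulator: no repeats, GC skew, multi-base
indels or rearrangements. Passing tests therefore demonstrate score
correctness of the dynamic program on sequences of controlled length and
divergence — which is a property of the recurrence, not of the input
distribution — but say nothing about, e.g., performance on repeat-rich
genomes. Correctness on real data is covered separately by the published
reference scores for NCBI record pairs (`swblock.validation`), which
require a one-time fetch of the records.

## Verification strategy

Three independent routes must agree: the naive full-matrix oracle, the
blocked engine at many block widths (including BW = 1 and BW > n), and —
for the oracle itself — Biopython's `PairwiseAligner` in local mode with
open = −(Go+Ge), extend = −Ge, whose gap model is identical. Randomized
sweeps (200 pairs, lengths 1–400, similarity 0–100%) check score *and*
argmax equality at every block width and admissible integer width; property
tests (hypothesis, derandomized) cover nonnegativity, the score bound,
symmetry, suffix monotonicity, padding invariance, self-alignment and the
E/F floor. Problem sizes in the default suite and the acceptance script
(up to 10 kb pairs, 10⁸ cells) were chosen so the whole verification runs
in seconds while still exercising multi-block, multi-boundary sweeps; the
worked README example runs a 10-gigacell pair in ~21 s.

## Known limitations

- Score-only: no traceback, no alignment coordinates beyond the argmax
  cell.
- match ≤ 0 schemes are rejected (the a-priori bound needs match > 0).
- Only match/mismatch substitution scoring — no 4×4 or protein matrices.
- Single-threaded; throughput (~0.2–0.5 GCUPS) is what one CPU core of
  compiled row-sweep code delivers, orders of magnitude below accelerator
  implementations of the same blocking scheme.
- The N-scores-as-mismatch rule is a convention; tools that score
  ambiguity codes specially may disagree on records containing N runs.
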