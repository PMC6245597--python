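"""Affine-gap Smith-Waterman scoring: reference oracle and blocked engine.

The local-alignment score of two DNA sequences S1 (length m) and S2 (length
n) is the maximum over the similarity matrix H defined by the affine-gap
(Gotoh) recurrences

    H[i,j] = max(0, H[i-1,j-1] + SM(S1[i], S2[j]), E[i,j], F[i,j])
    E[i,j] = max(H[i,j-1] - (Go+Ge), E[i,j-1] - Ge)
    F[i,j] = max(H[i-1,j] - (Go+Ge), F[i-1,j] - Ge)

with H, E and F all 0 when i=0 or j=0, SM the match/mismatch substitution
score, and Go/Ge the gap-open and gap-extension penalties (a gap of length k
costs Go + k*Ge).

Two engines compute this score:

* :func:`sw_score_full` — the naive full-matrix oracle, O(m*n) memory, for
  small inputs and for validating everything else.
* :func:`sw_score_blocked` — the production engine.  H is divided into
  vertical blocks of BW columns; each block is processed top-to-bottom,
  left-to-right with O(BW) row buffers for H and F, and adjacent blocks
  exchange only the last-column H and E vectors (double-buffered, swapped
  after every block).  Memory is O(m + BW) regardless of n, so arbitrarily
  long targets fit.

Scores are a-priori bounded by min(m,n)*match (for match>0); the bound is
checked against the maximum value representable at the configured integer
width (127 / 32767 / 2147483647 for 8/16/32 bits) and inadmissible runs are
refused rather than silently overflowing — see :func:`check_width`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "PAD_RESIDUE",
    "INT_MAX",
    "ScoringScheme",
    "Sequence",
    "KernelConfig",
    "BlockBoundary",
    "AlignmentResult",
    "ConfigurationError",
    "WidthOverflowError",
    "sw_score_full",
    "sw_score_blocked",
    "process_block",
    "pad_target",
    "check_width",
    "min_int_width",
    "gcups",
]

#: Reserved pad symbol appended to the target so its length becomes a
#: multiple of the block width.  Non-ACGT, so it scores `mismatch` against
#: every residue including itself and provably cannot raise the maximum.
PAD_RESIDUE = "X"

#: Largest score representable at each supported integer width.
INT_MAX = {8: 127, 16: 32767, 32: 2147483647}

# residue -> code lookup: A=0 C=1 G=2 T=3, everything else 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


class ConfigurationError(ValueError):
    """Inconsistent engine configuration (e.g. boundary length mismatch)."""


class WidthOverflowError(OverflowError):
    """The requested integer width cannot represent the score bound."""

    def __init__(self, bound: int, int_width: int, min_width: int | None):
        self.bound = bound
        self.int_width = int_width
        self.min_width = min_width
        if min_width is None:
            hint = "no supported width admits it"
        else:
            hint = f"minimum admissible width is {min_width} bits"
        super().__init__(
            f"score bound {bound} exceeds the {int_width}-bit maximum "
            f"{INT_MAX[int_width]}; {hint}"
        )


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and affine gap penalties.

    ``gap_open`` and ``gap_extend`` are stored as nonnegative magnitudes and
    subtracted by the recurrences; the conventional DNA parameters
    (+1, -3, -5, -2) are therefore ``ScoringScheme(1, -3, 5, 2)``.
    """

    match: int = 1
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative magnitudes")

    def substitution(self, a: str, b: str) -> int:
        """SM(a, b): `match` iff a == b over {A,C,G,T}, else `mismatch`."""
        if a == b and a in "ACGT":
            return self.match
        return self.mismatch


@dataclass(frozen=True)
class Sequence:
    """A validated DNA residue string with an identifier.

    Residues are uppercase letters; non-ACGT letters (N, IUPAC ambiguity
    codes, the pad symbol) are legal and score `mismatch` against everything.
    """

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues.isupper() and self.residues:
            object.__setattr__(self, "residues", self.residues.upper())
        if self.residues and not self.residues.isalpha():
            bad = sorted({c for c in self.residues if not c.isalpha()})
            raise ValueError(f"illegal residue character(s): {bad!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def codes(self) -> np.ndarray:
        """uint8 encoding (A=0, C=1, G=2, T=3, other=4) used by the kernels."""
        raw = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        return _CODE[raw]


@dataclass(frozen=True)
class KernelConfig:
    """Blocked-engine configuration: block width and emulated integer width."""

    block_width: int = 512
    int_width: int = 32
    max_value: int = field(init=False)

    def __post_init__(self):
        if self.block_width < 1:
            raise ConfigurationError("block_width must be >= 1")
        if self.int_width not in INT_MAX:
            raise ConfigurationError(
                f"int_width must be one of {sorted(INT_MAX)}, got {self.int_width}"
            )
        object.__setattr__(self, "max_value", INT_MAX[self.int_width])


@dataclass
class BlockBoundary:
    """Last-column H and E values of a block, rows 1..m.

    A zero-filled boundary encodes the j=0 initialisation column.
    """

    h_col: np.ndarray
    e_col: np.ndarray

    @classmethod
    def zero(cls, m: int) -> "BlockBoundary":
        return cls(np.zeros(m, np.int64), np.zeros(m, np.int64))

    def __len__(self) -> int:
        return len(self.h_col)


@dataclass
class AlignmentResult:
    """Optimal local score plus bookkeeping.

    ``max_i``/``max_j`` are the 1-based coordinates of the first maximal cell
    in row-major order over the unpadded m x n matrix; both are 0 when the
    score is 0 (no positive cell, hence no alignment locus).  ``cells`` is
    m*n for the unpadded lengths and ``gcups`` is cells / (runtime_s * 1e9).
    """

    score: int
    max_i: int
    max_j: int
    m: int
    n: int
    cells: int
    runtime_s: float
    gcups: float


def gcups(m: int, n: int, t: float) -> float:
    """Billions of cell updates per second: (m*n) / (t*1e9)."""
    if t <= 0:
        raise ValueError("runtime must be positive")
    return (m * n) / (t * 1e9)


def min_int_width(bound: int) -> int | None:
    """Smallest supported width whose maximum admits `bound`, or None."""
    for w in sorted(INT_MAX):
        if bound <= INT_MAX[w]:
            return w
    return None


def check_width(s1_len: int, s2_len: int, scheme: ScoringScheme,
                config: KernelConfig) -> tuple[bool, int]:
    """A-priori overflow guard.

    The score can never exceed ``min(m, n) * match`` (for match > 0: at most
    min(m,n) aligned pairs, each contributing at most `match`).  Returns
    ``(admissible, bound)`` where admissible means the bound fits the
    configured width's maximum value.
    """
    if scheme.match <= 0:
        raise ValueError("check_width requires match > 0")
    bound = min(s1_len, s2_len) * scheme.match
    return bound <= config.max_value, bound


def pad_target(s2: Sequence, block_width: int) -> Sequence:
    """Extend s2 with pad residues to the next multiple of `block_width`.

    Pad residues score `mismatch` against everything, so padding never
    changes the optimal score or its position.
    """
    if block_width < 1:
        raise ConfigurationError("block_width must be >= 1")
    rem = len(s2) % block_width
    if rem == 0:
        return s2
    return Sequence(s2.id, s2.residues + PAD_RESIDUE * (block_width - rem))


def sw_score_full(s1: Sequence, s2: Sequence,
                  scheme: ScoringScheme) -> AlignmentResult:
    """Reference oracle: full-matrix affine-gap local alignment score.

    Materialises the complete H matrix (O(m*n) memory) — intended for small
    inputs and as the ground truth the blocked engine is validated against.
    """
    m, n = len(s1), len(s2)
    t0 = time.perf_counter()
    if m == 0 or n == 0:
        score, mi, mj = 0, 0, 0
    else:
        H, _, _ = _kernels.full_matrices(
            s1.codes(), s2.codes(),
            scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend,
        )
        score = int(H.max())
        if score == 0:
            mi, mj = 0, 0
        else:
            flat = int(np.argmax(H))  # first maximum in row-major order
            mi, mj = divmod(flat, n + 1)
    elapsed = time.perf_counter() - t0
    return AlignmentResult(
        score=score, max_i=mi, max_j=mj, m=m, n=n, cells=m * n,
        runtime_s=elapsed,
        gcups=gcups(m, n, elapsed) if m and n and elapsed > 0 else 0.0,
    )


def sw_matrices(s1: Sequence, s2: Sequence,
                scheme: ScoringScheme) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full H, E, F matrices (shape (m+1, n+1), zero borders) for inspection."""
    return _kernels.full_matrices(
        s1.codes(), s2.codes(),
        scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend,
    )


def process_block(s1: Sequence, s2_block: Sequence, scheme: ScoringScheme,
                  boundary_in: BlockBoundary, config: KernelConfig,
                  ) -> tuple[BlockBoundary, int, tuple[int, int]]:
    """Compute one BW-wide vertical block of the H matrix.

    ``boundary_in`` supplies the previous block's last-column H and E values
    (rows 1..m); the block is scanned row by row, top to bottom and left to
    right, keeping only O(BW) row buffers for H and F.  Returns the block's
    own last-column boundary, its maximum H value, and the first maximal
    cell ``(i, jj)`` in scan order (jj 1-based within the block; (0, 0) when
    the block maximum is 0).
    """
    m = len(s1)
    if len(boundary_in) != m:
        raise ConfigurationError(
            f"boundary length {len(boundary_in)} != |S1| = {m}"
        )
    if len(s2_block) != config.block_width:
        raise ConfigurationError(
            f"block length {len(s2_block)} != block_width {config.block_width}"
        )
    h_out = np.empty(m, np.int64)
    e_out = np.empty(m, np.int64)
    best, bi, bj = _kernels.block_kernel(
        s1.codes(), s2_block.codes(),
        scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend,
        boundary_in.h_col, boundary_in.e_col, h_out, e_out,
    )
    return BlockBoundary(h_out, e_out), int(best), (int(bi), int(bj))


def sw_score_blocked(s1: Sequence, s2: Sequence, scheme: ScoringScheme,
                     config: KernelConfig | None = None) -> AlignmentResult:
    """Blocked score engine: identical result to :func:`sw_score_full`.

    Pads the target to a multiple of ``config.block_width``, sweeps the
    ceil(n/BW) vertical blocks left to right, and carries the last-column
    H/E boundary between blocks in a double-buffered read/write pair swapped
    after each block.  Raises :class:`WidthOverflowError` when the a-priori
    score bound exceeds the configured integer width's maximum.
    """
    if config is None:
        config = KernelConfig()
    m, n = len(s1), len(s2)
    admissible, bound = check_width(m, n, scheme, config)
    if not admissible:
        raise WidthOverflowError(bound, config.int_width, min_int_width(bound))

    t0 = time.perf_counter()
    score, gi, gj = 0, 0, 0
    if m > 0 and n > 0:
        if n % config.block_width != 0 and scheme.mismatch >= 0:
            # pad residues must strictly lose score or they could
            # fabricate a maximum inside a pad column
            raise ConfigurationError(
                "padding requires mismatch < 0; raise block_width to divide "
                "the target length instead"
            )
        bw = config.block_width
        s1_codes = s1.codes()
        s2_codes = pad_target(s2, bw).codes()
        args = (scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
        h_read = np.zeros(m, np.int64)
        e_read = np.zeros(m, np.int64)
        h_write = np.empty(m, np.int64)
        e_write = np.empty(m, np.int64)
        for b in range(len(s2_codes) // bw):
            block = s2_codes[b * bw:(b + 1) * bw]
            bmax, bi, bj = _kernels.block_kernel(
                s1_codes, block, *args, h_read, e_read, h_write, e_write,
            )
            # first maximal cell in row-major (i, then j) order; blocks to
            # the right can only win a tie with a strictly smaller row
            if bmax > score or (bmax == score and bmax > 0 and bi < gi):
                score, gi, gj = int(bmax), int(bi), b * bw + int(bj)
            h_read, h_write = h_write, h_read
            e_read, e_write = e_write, e_read
        score = int(score)
    elapsed = time.perf_counter() - t0
    return AlignmentResult(
        score=score, max_i=gi, max_j=gj, m=m, n=n, cells=m * n,
        runtime_s=elapsed,
        gcups=gcups(m, n, elapsed) if m and n and elapsed > 0 else 0.0,
    )
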