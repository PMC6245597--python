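"""Seeded synthetic DNA pair generator.

Emulates the engine's intended workload — pairs of long DNA sequences whose
similarity ranges from essentially unrelated to near-identical — without any
downloads.  A uniform random sequence is mutated by a single per-position
pass: each position is deleted with probability ``deletion_rate``, otherwise
substituted to a uniformly chosen *different* residue with probability
``substitution_rate``; after every original position one uniform residue is
inserted with probability ``insertion_rate``.  Everything is deterministic
under ``MutationModel.seed``.

This is deliberately not an evolutionary model (no repeats, GC skew, or
rearrangements); it only provides coarse, reproducible similarity control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Sequence

__all__ = ["MutationModel", "random_dna", "mutate", "make_pair"]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i

# fixed stream key so mutate() draws are independent of the random_dna()
# draws made from the same seed
_MUTATE_STREAM = 0x6D75


@dataclass(frozen=True)
class MutationModel:
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        rates = (self.substitution_rate, self.insertion_rate,
                 self.deletion_rate)
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if sum(rates) > 1:
            raise ValueError("substitution + insertion + deletion rates "
                             "must sum to at most 1")


def random_dna(length: int, seed: int, id: str = "synthetic") -> Sequence:
    """Uniform i.i.d. sequence over {A,C,G,T}, reproducible under `seed`."""
    if length < 0:
        raise ValueError("length must be nonnegative")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length)
    return Sequence(id, _ALPHABET[codes].tobytes().decode("ascii"))


def mutate(s: Sequence, model: MutationModel) -> Sequence:
    """Apply one per-position substitution/indel pass to `s`.

    Substitutions always change the residue (uniform over the three other
    bases; non-ACGT residues are replaced by a uniform base).  Insertions
    place one uniform residue after the position they follow.
    """
    rng = np.random.default_rng([model.seed, _MUTATE_STREAM])
    n = len(s)
    if n == 0:
        return Sequence(f"{s.id}_mut", "")
    codes = _CODE[np.frombuffer(s.residues.encode("ascii"), dtype=np.uint8)]

    u = rng.random(n)
    deleted = u < model.deletion_rate
    substituted = (~deleted) & (u < model.deletion_rate + model.substitution_rate)
    inserted = rng.random(n) < model.insertion_rate

    new_codes = codes.astype(np.int64)
    # shift by 1..3 (mod 4) guarantees a different base; non-ACGT -> uniform
    shift = rng.integers(1, 4, size=n)
    sub_vals = (new_codes + shift) % 4
    sub_vals[codes >= 4] = rng.integers(0, 4, size=int((codes >= 4).sum()))
    new_codes[substituted] = sub_vals[substituted]
    ins_vals = rng.integers(0, 4, size=n)

    kept = ~deleted
    counts = kept.astype(np.int64) + inserted.astype(np.int64)
    ends = np.cumsum(counts)
    out = np.empty(int(ends[-1]), dtype=np.uint8)
    starts = ends - counts
    out[starts[kept]] = new_codes[kept].astype(np.uint8)
    out[ends[inserted] - 1] = ins_vals[inserted].astype(np.uint8)
    return Sequence(f"{s.id}_mut", _ALPHABET[out].tobytes().decode("ascii"))


def make_pair(length: int, model: MutationModel) -> tuple[Sequence, Sequence]:
    """A random sequence and its mutated copy (both seeded by the model)."""
    original = random_dna(length, model.seed)
    return original, mutate(original, model)
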