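import numpy as np
import pytest

from swblock import MutationModel, ScoringScheme, Sequence, make_pair, random_dna


@pytest.fixture(scope="session")
def scheme():
    """The conventional DNA scoring parameters (+1, -3, -5, -2)."""
    return ScoringScheme(match=1, mismatch=-3, gap_open=5, gap_extend=2)


def random_pair(seed: int, max_len: int = 400) -> tuple[Sequence, Sequence]:
    """A seeded pair whose similarity spans unrelated to identical.

    Cycles through three regimes: unrelated uniform sequences, mutated
    copies at a seeded divergence, and identical copies.
    """
    rng = np.random.default_rng(seed)
    length = int(rng.integers(1, max_len + 1))
    regime = seed % 3
    if regime == 0:  # unrelated
        return (random_dna(length, seed * 2 + 1, id="q"),
                random_dna(int(rng.integers(1, max_len + 1)), seed * 2 + 2,
                           id="t"))
    if regime == 1:  # diverged copy
        model = MutationModel(
            substitution_rate=float(rng.uniform(0, 0.5)),
            insertion_rate=float(rng.uniform(0, 0.15)),
            deletion_rate=float(rng.uniform(0, 0.15)),
            seed=seed,
        )
        s, t = make_pair(length, model)
        if len(t) == 0:
            t = Sequence("t", "A")
        return s, t
    s = random_dna(length, seed, id="q")  # identical
    return s, Sequence("t", s.residues)
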