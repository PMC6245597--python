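"""Validation against published optimal scores for real NCBI sequence pairs.

The engine's correctness on real data is checked against optimal local
alignment scores published for pairs of NCBI nucleotide records under the
scoring scheme (+1, -3, -5, -2).  The records themselves are not bundled
(they range from 10 kilobases to megabases); fetch them once with e.g.

    efetch -db nuccore -id AF133821.1 -format fasta > AF133821.1.fasta

(or the equivalent E-utilities URL) into a directory, then run
:func:`score_reference_pair` or ``scripts/acceptance.py`` pointing at it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .core import KernelConfig, ScoringScheme, sw_score_blocked
from .io import read_fasta

__all__ = ["ReferencePair", "REFERENCE_PAIRS", "score_reference_pair"]


@dataclass(frozen=True)
class ReferencePair:
    accession1: str
    accession2: str
    expected_score: int


#: NCBI pairs with published optimal scores under ScoringScheme(1, -3, 5, 2),
#: ordered by matrix size (100K .. 1G cells).
REFERENCE_PAIRS = (
    ReferencePair("AF133821.1", "AY352275.1", 5027),
    ReferencePair("NC_001715.1", "AF494279.1", 51),
    ReferencePair("NC_000898", "NC_007605", 18),
    ReferencePair("NC_003064.2", "NC_000914.1", 48),
    ReferencePair("CP000051.1", "AE002160.2", 82091),
)


def score_reference_pair(data_dir: str | Path, pair: ReferencePair,
                         block_width: int = 512) -> int:
    """Score one reference pair from locally fetched FASTA files.

    Expects ``<data_dir>/<accession>.fasta`` for both accessions; returns the
    blocked engine's optimal score (to be compared with
    ``pair.expected_score``).
    """
    data_dir = Path(data_dir)
    s1 = read_fasta(data_dir / f"{pair.accession1}.fasta")
    s2 = read_fasta(data_dir / f"{pair.accession2}.fasta")
    result = sw_score_blocked(
        s1, s2, ScoringScheme(1, -3, 5, 2),
        KernelConfig(block_width=block_width, int_width=32),
    )
    return result.score
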