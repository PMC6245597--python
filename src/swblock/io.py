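"""FASTA reading and structured result writing.

Reading goes through Biopython's FASTA parser; records are validated into
:class:`~swblock.core.Sequence` objects (uppercased, letters only — '*' and
'-' are rejected rather than silently dropped, since gap/stop characters in
DNA input almost always indicate an upstream mistake).

Results are written either as a single-header single-row TSV or as a flat
JSON object; GCUPS is reported with 2 decimals in both.
"""

from __future__ import annotations

import io as _io
import json
from os import PathLike
from typing import TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AlignmentResult, KernelConfig, ScoringScheme, Sequence

__all__ = [
    "FastaFormatError",
    "UnknownRecordError",
    "IllegalResidueError",
    "read_fasta",
    "write_fasta",
    "write_result",
    "RESULT_FIELDS",
]


class FastaFormatError(ValueError):
    """Input is not FASTA (no '>' header)."""


class UnknownRecordError(KeyError):
    """No record with the requested id exists in the file."""


class IllegalResidueError(ValueError):
    """A sequence character outside the accepted residue alphabet."""


def _validate_residues(record_id: str, residues: str) -> str:
    residues = residues.upper()
    bad = sorted({c for c in residues if not ("A" <= c <= "Z" or c in "*-")})
    if bad:
        raise IllegalResidueError(
            f"record {record_id!r}: illegal character(s) {''.join(bad)!r}"
        )
    if "*" in residues or "-" in residues:
        raise IllegalResidueError(
            f"record {record_id!r}: gap/stop characters ('-', '*') are not "
            "accepted in DNA input"
        )
    return residues


def read_fasta(source: str | PathLike | TextIO,
               record_id: str | None = None) -> Sequence:
    """Read one record from a FASTA file or text stream.

    Returns the record whose id (header token up to the first whitespace)
    equals ``record_id``, or the first record when no id is given.  Raises
    :class:`FastaFormatError` for non-FASTA input, :class:`UnknownRecordError`
    for a missing id and :class:`IllegalResidueError` for characters outside
    the residue alphabet.  Missing files raise the usual ``OSError``.
    """
    if hasattr(source, "read"):
        handle = source
        close = False
    else:
        handle = open(source, "r", encoding="ascii")
        close = True
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()

    stripped = text.lstrip()
    if not stripped.startswith(">"):
        raise FastaFormatError("input does not start with a '>' FASTA header")

    seen = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if record_id is None or rec.id == record_id:
            return Sequence(rec.id, _validate_residues(rec.id, str(rec.seq)))
        seen.append(rec.id)
    if record_id is None:
        raise FastaFormatError("FASTA input contains no records")
    raise UnknownRecordError(
        f"no record {record_id!r} (found: {', '.join(seen) or 'none'})"
    )


def write_fasta(seq: Sequence, path: str | PathLike,
                description: str = "") -> None:
    """Write one sequence as a standard wrapped FASTA file."""
    rec = SeqRecord(Seq(seq.residues), id=seq.id, description=description)
    SeqIO.write([rec], str(path), "fasta")


#: Column order of the TSV output / key order of the JSON output.
RESULT_FIELDS = (
    "score", "max_i", "max_j", "m", "n", "cells", "runtime_s", "gcups",
    "match", "mismatch", "gap_open", "gap_extend", "block_width", "int_width",
)


def _result_mapping(result: AlignmentResult, scheme: ScoringScheme,
                    config: KernelConfig) -> dict:
    return {
        "score": result.score,
        "max_i": result.max_i,
        "max_j": result.max_j,
        "m": result.m,
        "n": result.n,
        "cells": result.cells,
        "runtime_s": round(result.runtime_s, 6),
        "gcups": round(result.gcups, 2),
        "match": scheme.match,
        "mismatch": scheme.mismatch,
        "gap_open": scheme.gap_open,
        "gap_extend": scheme.gap_extend,
        "block_width": config.block_width,
        "int_width": config.int_width,
    }


def write_result(result: AlignmentResult, scheme: ScoringScheme,
                 config: KernelConfig, format: str = "tsv") -> str:
    """Render a result plus its parameters as TSV (header+row) or flat JSON.

    ``runtime_s`` is rounded to microseconds and ``gcups`` to 2 decimals;
    all other fields are exact integers.
    """
    mapping = _result_mapping(result, scheme, config)
    if format == "tsv":
        header = "\t".join(RESULT_FIELDS)
        row = "\t".join(str(mapping[k]) for k in RESULT_FIELDS)
        return f"{header}\n{row}\n"
    if format == "json":
        return json.dumps(mapping, indent=2) + "\n"
    raise ValueError(f"unknown result format {format!r} (use 'tsv' or 'json')")
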