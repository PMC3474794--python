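"""FASTA input/output and basic sequence plumbing.

Sequences are normalized to the 5-letter alphabet {A, C, G, T, N}:
lowercase input is uppercased and every IUPAC ambiguity code other than
A/C/G/T collapses to N.  The composition models downstream work on a
4-letter alphabet and skip N-containing windows, so nothing finer than
"ambiguous" needs to be preserved.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import FastaFormatError

__all__ = [
    "SequenceRecord",
    "normalize_residues",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "filter_by_length",
]

_KEEP = set("ACGT")
# byte-level translation: uppercase handled first, then non-ACGT -> N
_NORM_TABLE = bytes(
    (c if chr(c) in _KEEP else ord("N")) for c in range(256)
)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_residues(raw: str) -> str:
    """Uppercase and collapse non-ACGT symbols (IUPAC codes, U, ...) to N."""
    return raw.upper().encode("ascii", errors="replace").translate(_NORM_TABLE).decode("ascii")


@dataclass
class SequenceRecord:
    """A single nucleotide sequence with a unique id and free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = normalize_residues(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Records are returned in file order.  An empty file yields an empty list.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FastaFormatError
        If a record has an empty id or an empty sequence (the error message
        names the 0-based record index).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise FastaFormatError(f"record {i} in {path} has an empty id")
        if len(rec.seq) == 0:
            raise FastaFormatError(f"record {i} ({rec.id}) in {path} has an empty sequence")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA, wrapping sequence lines at 70 columns."""
    bio = (
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    )
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=70).write_file(bio)


def reverse_complement(residues: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    return residues.translate(_COMPLEMENT)[::-1]


def filter_by_length(
    records: Sequence[SequenceRecord],
    min_length: int,
    strict: bool = False,
) -> list[SequenceRecord]:
    """Keep records at least (``strict=False``) or strictly longer than
    (``strict=True``) *min_length* bases, preserving order.

    The two modes mirror the two thresholds of the pipeline: viral contigs
    are kept at >= 5 kb (inclusive) while cellular scaffolds must exceed
    100 kb (exclusive).
    """
    if min_length < 0:
        raise ValueError("min_length must be non-negative")
    if strict:
        return [r for r in records if r.length > min_length]
    return [r for r in records if r.length >= min_length]
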