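"""FASTA input/output with IUPAC nucleotide validation.

All sequences handled by the package are DNA over the 15-letter IUPAC
ambiguity alphabet (A, C, G, T plus R, Y, S, W, K, M, B, D, H, V, N).
Residues are uppercased on ingest and RNA uracil is normalized to thymine,
so downstream code only ever sees uppercase DNA codes.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

PathOrStream = Union[str, PathLike, IO[str]]


class FastaFormatError(ValueError):
    """Raised when the input text is not parseable FASTA."""


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside the IUPAC set."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named IUPAC nucleotide sequence.

    Parameters
    ----------
    identifier : str
        Non-empty token (the FASTA header up to the first whitespace).
    description : str
        Remainder of the header line; may be empty.
    residues : str
        Uppercase IUPAC nucleotide codes; U is normalized to T.
    """

    identifier: str
    description: str = ""
    residues: str = field(default="")

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("record identifier must be non-empty")
        normalized = self.residues.upper().replace("U", "T")
        bad = set(normalized) - IUPAC_CODES
        if bad:
            raise AlphabetError(
                f"record {self.identifier!r} contains non-IUPAC character(s): "
                + ", ".join(sorted(repr(c) for c in bad))
            )
        if not normalized:
            raise ValueError(f"record {self.identifier!r} has an empty sequence")
        object.__setattr__(self, "residues", normalized)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def _open_text(source: PathOrStream, mode: str = "rt") -> IO[str]:
    if hasattr(source, "read") or hasattr(source, "write"):
        return source  # already a stream
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_stream(handle: IO[str]) -> Iterator[SequenceRecord]:
    # Reject sequence text appearing before any header; SimpleFastaParser
    # silently skips it, so peek at the first non-blank line ourselves.
    text = handle.read()
    for line in text.splitlines():
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaFormatError(
                "sequence data encountered before the first '>' header"
            )
        break
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        parts = title.split(maxsplit=1)
        if not parts:
            raise FastaFormatError("encountered a FASTA record with an empty header")
        identifier = parts[0]
        description = parts[1] if len(parts) > 1 else ""
        yield SequenceRecord(identifier, description, seq.replace(" ", ""))


def read_fasta(source: PathOrStream) -> list[SequenceRecord]:
    """Read FASTA records from a path (``.gz`` detected by suffix) or text stream.

    Returns records in file order with residues uppercased and U mapped to T.
    An empty stream yields an empty list. Raises :class:`AlphabetError` for
    non-IUPAC characters and :class:`FastaFormatError` for malformed input.
    """
    handle = _open_text(source, "rt")
    own = handle is not source
    try:
        return list(_parse_stream(handle))
    finally:
        if own:
            handle.close()


def iter_fasta(source: PathOrStream) -> Iterator[SequenceRecord]:
    """Iterate FASTA records lazily; see :func:`read_fasta`."""
    handle = _open_text(source, "rt")
    own = handle is not source
    try:
        yield from _parse_stream(handle)
    finally:
        if own:
            handle.close()


def write_fasta(
    records: Iterable[SequenceRecord],
    destination: PathOrStream,
    line_width: int = 60,
) -> int:
    """Write records as wrapped FASTA; returns the number of records written.

    Round-trips with :func:`read_fasta` on identifier, description and residues.
    """
    if line_width < 1:
        raise ValueError("line_width must be positive")
    handle = _open_text(destination, "wt")
    own = handle is not destination
    n = 0
    try:
        for rec in records:
            header = rec.identifier if not rec.description else f"{rec.identifier} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), line_width):
                handle.write(rec.residues[i : i + line_width] + "\n")
            n += 1
    finally:
        if own:
            handle.close()
    return n
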