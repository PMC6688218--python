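"""Sequence file I/O: FASTA/FASTQ, plain or gzip-compressed.

Thin wrappers over Biopython's fast tuple iterators. All readers are
case-insensitive with respect to sequence content (sequences are returned
upper-cased) and accept multi-line records.
"""

from __future__ import annotations

import gzip
import os
from typing import Iterable, Iterator, Tuple

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "open_text",
    "sniff_format",
    "iter_sequences",
    "read_fasta",
    "write_fasta",
]


def open_text(path: str | os.PathLike, mode: str = "rt"):
    """Open ``path`` as text, transparently decompressing ``.gz`` files."""
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def sniff_format(path: str | os.PathLike) -> str:
    """Return ``"fasta"`` or ``"fastq"`` from the first record character."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"sequence file not found: {path}")
    with open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise ValueError(f"unrecognized sequence format in {path!r}: "
                             f"first record starts with {line[0]!r}")
    raise ValueError(f"empty sequence file: {path}")


def iter_sequences(path: str | os.PathLike) -> Iterator[Tuple[str, str]]:
    """Yield ``(name, sequence)`` for every record, format auto-detected.

    The name is the header token up to the first whitespace; the sequence
    is upper-cased.
    """
    fmt = sniff_format(path)
    with open_text(path) as fh:
        if fmt == "fasta":
            for header, seq in SimpleFastaParser(fh):
                yield header.split()[0], seq.upper()
        else:
            for header, seq, _qual in FastqGeneralIterator(fh):
                yield header.split()[0], seq.upper()


def read_fasta(path: str | os.PathLike) -> list[Tuple[str, str]]:
    records = list(iter_sequences(path))
    if not records:
        raise ValueError(f"empty sequence file: {path}")
    return records


def write_fasta(records: Iterable[Tuple[str, str]],
                path: str | os.PathLike, width: int = 80) -> None:
    """Write ``(name, sequence)`` pairs as (optionally gzipped) FASTA."""
    with open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width])
                fh.write("\n")
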