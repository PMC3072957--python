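"""Streaming FASTA/FASTQ reading and writing in batches.

Parsing is delegated to Biopython's low-level iterators
(``SimpleFastaParser`` / ``FastqGeneralIterator``), which stream without
building SeqRecord objects.  Files ending in ``.gz`` are transparently
decompressed/compressed.  The format is sniffed from the first byte
('>' FASTA, '@' FASTQ) unless given explicitly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["ReadRecord", "read_stream", "write_stream"]

FASTA_WRAP = 60  # column width for wrapped FASTA output


@dataclass
class ReadRecord:
    """One sequencing read: identifier, sequence, optional quality string."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self):
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _sniff_format(path) -> str:
    with _open_text(path, "r") as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    if first == "":
        return "fasta"  # empty file; parses to an empty iterator either way
    raise ValueError(f"{path}: cannot sniff format from first byte {first!r}")


def read_stream(
    path, format: str = "auto", batch_size: int = 65536
) -> Iterator[list[ReadRecord]]:
    """Yield batches of :class:`ReadRecord` from a FASTA/FASTQ(.gz) file.

    Order is preserved, multi-line FASTA sequences are concatenated, and the
    final partial batch is emitted.  Malformed records raise ``ValueError``
    carrying the file path.
    """
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    batch: list[ReadRecord] = []
    with _open_text(path, "r") as fh:
        try:
            if fmt == "fasta":
                records = (
                    ReadRecord(id=title.split()[0] if title else "", sequence=seq)
                    for title, seq in SimpleFastaParser(fh)
                )
            else:
                records = (
                    ReadRecord(id=title.split()[0], sequence=seq, quality=qual)
                    for title, seq, qual in FastqGeneralIterator(fh)
                )
            for rec in records:
                batch.append(rec)
                if len(batch) >= batch_size:
                    yield batch
                    batch = []
        except ValueError as err:
            raise ValueError(f"{path}: malformed {fmt} record: {err}") from err
    if batch:
        yield batch


def write_stream(records: Iterable[ReadRecord], path, format: str = "auto") -> int:
    """Write records as FASTA or FASTQ(.gz); returns the number written.

    With ``format='auto'`` the format follows the file extension.  FASTA
    output drops qualities and wraps sequences; FASTQ output requires a
    quality on every record and writes standard 4-line records.
    """
    fmt = format
    if fmt == "auto":
        stem = Path(path)
        if stem.suffix == ".gz":
            stem = stem.with_suffix("")
        fmt = {
            ".fa": "fasta",
            ".fasta": "fasta",
            ".fna": "fasta",
            ".fq": "fastq",
            ".fastq": "fastq",
        }.get(stem.suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path}")
    n = 0
    with _open_text(path, "w") as fh:
        for rec in records:
            if fmt == "fasta":
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.sequence), FASTA_WRAP):
                    fh.write(rec.sequence[i : i + FASTA_WRAP] + "\n")
            else:
                if rec.quality is None:
                    raise ValueError(f"read {rec.id!r} has no quality for FASTQ output")
                fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n
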