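"""FASTA/FASTQ/TSV I/O helpers (thin wrappers over Biopython parsers)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Tuple

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path) -> Iterator[Tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ file (gzip allowed).

    Truncated or malformed records raise ValueError carrying the index of
    the offending record.
    """
    i = 0
    with _open_text(path) as fh:
        try:
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq
                i += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {i} in {path}: {exc}") from exc


def read_fasta(path) -> Iterator[Tuple[str, str]]:
    """Yield (id, sequence) from a FASTA file (gzip allowed)."""
    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            yield title.split()[0], seq


def read_seqs(path) -> Iterator[Tuple[str, str]]:
    """Dispatch on file content: FASTQ if it starts with '@', else FASTA."""
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(path, records: Iterable[Tuple[str, str]], width: int = 0) -> int:
    """Write (id, seq) records; width=0 keeps each sequence on one line."""
    n = 0
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            if width:
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
            else:
                fh.write(seq + "\n")
            n += 1
    return n


def write_fastq(path, records: Iterable[Tuple[str, str]], quality_char: str = "?") -> int:
    """Write (id, seq) records with a constant placeholder quality (Q30)."""
    n = 0
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n
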