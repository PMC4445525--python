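"""Sequence records, coordinate conventions, and FASTA/FASTQ input/output.

Conventions used throughout the package:

* Coordinates are 1-based, inclusive, on the positive (assembled) strand.
* Sequences are upper-case DNA over the alphabet ``{A, C, G, T, N}``.
* Reads are single-end; the sequencer reports each read 5'->3' on whichever
  strand it came from, so a negative-strand read is the reverse complement
  of the positive-strand sequence it covers.

Parsing is delegated to Biopython's low-level FASTA/FASTQ iterators; this
module only adds validation, streaming and the coordinate conventions.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "DNA_ALPHABET",
    "AlphabetError",
    "FormatError",
    "GenomeRecord",
    "SequenceRead",
    "ReadSetStats",
    "read_fasta",
    "write_fasta",
    "read_reads",
    "write_fastq",
    "reverse_complement",
    "compute_read_stats",
]

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file did not conform to the expected FASTA/FASTQ layout."""


class AlphabetError(ValueError):
    """A sequence contained characters outside {A, C, G, T, N}."""


def _check_alphabet(sequence: str, context: str) -> None:
    bad = set(sequence) - DNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{context}: invalid DNA character(s) {sorted(bad)!r}; "
            "only A, C, G, T, N are accepted (RNA 'U' is rejected)"
        )


@dataclass(frozen=True)
class GenomeRecord:
    """An assembled genome (or contig) with 1-based positive-strand coordinates.

    ``length`` is the genome length L used in the average-start-frequency
    formula Freq_ave = N_r / (2 L).
    """

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"genome record {self.identifier!r} has an empty sequence")
        _check_alphabet(self.sequence, f"genome record {self.identifier!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceRead:
    """A single sequencing read; quality is optional and unused by default."""

    identifier: str
    bases: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise FormatError(f"read {self.identifier!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise FormatError(
                f"read {self.identifier!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadSetStats:
    """Read-set summary: N_r (reads) and L_reads (mean read length, bp)."""

    read_count: int
    mean_read_length: float

    def __post_init__(self) -> None:
        if self.read_count < 0 or self.mean_read_length < 0:
            raise ValueError("read_count and mean_read_length must be non-negative")
        if (self.read_count == 0) != (self.mean_read_length == 0):
            raise ValueError("mean_read_length must be 0 exactly when read_count is 0")


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: PathLike) -> list[GenomeRecord]:
    """Read all records from a FASTA file (optionally gzipped).

    Sequences are upper-cased and validated as DNA; an empty file yields an
    empty list. Malformed input (text before the first header, empty
    sequences, non-DNA characters) raises :class:`FormatError` /
    :class:`AlphabetError` naming the offending record.
    """
    records: list[GenomeRecord] = []
    with _open_text(path) as handle:
        # SimpleFastaParser silently skips text before the first header;
        # treat such input as malformed instead.
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}: line {lineno} precedes the first '>' header")
            break
        handle.seek(0)
        try:
            for title, sequence in SimpleFastaParser(handle):
                identifier = title.split()[0] if title.split() else ""
                if not identifier:
                    raise FormatError(
                        f"{path}: record {len(records) + 1} has a malformed/empty header line"
                    )
                if not sequence:
                    raise FormatError(f"{path}: record {identifier!r} has an empty sequence")
                records.append(GenomeRecord(identifier, sequence.upper()))
        except ValueError as exc:
            if isinstance(exc, (FormatError, AlphabetError)):
                raise
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[GenomeRecord], path: PathLike, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for record in records:
            handle.write(f">{record.identifier}\n")
            seq = record.sequence
            for start in range(0, len(seq), width):
                handle.write(seq[start : start + width] + "\n")


def _infer_format(path: PathLike) -> str:
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    raise FormatError(f"cannot infer read format from file name {path!r}; pass format explicitly")


def read_reads(path: PathLike, format: Optional[str] = None) -> Iterator[SequenceRead]:
    """Stream reads from a FASTQ or FASTA file without loading them all.

    ``format`` is ``"fastq"`` or ``"fasta"``; when omitted it is inferred
    from the file extension. Truncated records and sequence/quality length
    mismatches raise :class:`FormatError` identifying the record.
    """
    fmt = format or _infer_format(path)
    if fmt not in ("fastq", "fasta"):
        raise ValueError(f"unknown read format {fmt!r}")
    with _open_text(path) as handle:
        n = 0
        try:
            if fmt == "fastq":
                for title, seq, qual in FastqGeneralIterator(handle):
                    n += 1
                    yield SequenceRead(title.split()[0], seq.upper(), qual)
            else:
                for title, seq in SimpleFastaParser(handle):
                    n += 1
                    if not seq:
                        raise FormatError(f"{path}: read {title.split()[0]!r} has an empty sequence")
                    yield SequenceRead(title.split()[0], seq.upper())
        except ValueError as exc:
            if isinstance(exc, (FormatError, AlphabetError)):
                raise
            raise FormatError(f"{path}: after record {n}: {exc}") from exc


def write_fastq(reads: Iterable[SequenceRead], path: PathLike, default_quality: str = "I") -> None:
    """Write 4-line FASTQ; reads without quality get a constant quality string."""
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = read.quality if read.quality is not None else default_quality * len(read.bases)
            handle.write(f"@{read.identifier}\n{read.bases}\n+\n{qual}\n")


def reverse_complement(bases: str) -> str:
    """Watson-Crick reverse complement; N maps to N; case preserved."""
    _check_alphabet(bases.upper(), "reverse_complement input")
    return bases.translate(_COMPLEMENT)[::-1]


def compute_read_stats(lengths: Sequence[int]) -> ReadSetStats:
    """Summarise read lengths into (N_r, L_reads)."""
    n = len(lengths)
    mean = float(sum(lengths)) / n if n else 0.0
    return ReadSetStats(read_count=n, mean_read_length=mean)
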