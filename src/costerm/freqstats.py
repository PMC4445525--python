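"""Read-start frequency statistics for termini detection.

The core quantities, for m identical packaged genomes of length L sequenced
into N_r reads of mean length L_reads:

* ``Freq_ter = m`` — every mature genome contributes exactly one read
  starting at each natural terminus, so a terminal start-position count
  equals the number of sequenced genome copies.
* ``Freq_ave = N_r / (2 L)`` — reads start anywhere on either strand, so an
  ordinary position on one strand collects N_r / (2 L) starts on average.
* ``R = Freq_ter / Freq_ave = 2 m L / N_r = 2 L_reads`` — the expected
  peak-to-background ratio, a few hundred for typical read lengths, which
  is what makes termini detectable from read frequencies alone.

Counting is over fixed-length read-start prefixes (default 20 nt) rather
than whole identical reads: terminal reads share an exact 5' start but have
ragged 3' ends, and whole-read identity would fragment the terminal count
across read lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .seqcore import PathLike, SequenceRead

__all__ = [
    "StartFrequencyTable",
    "RatioResult",
    "count_start_prefixes",
    "average_start_frequency",
    "terminal_ratio",
    "theoretical_ratio",
    "rank_frequencies",
    "frequency_histogram",
    "matched_percentage",
    "write_ranked_tsv",
    "summary_dict",
]

DEFAULT_PREFIX_LENGTH = 20


@dataclass
class StartFrequencyTable:
    """Counts of read-start prefixes.

    ``total_reads`` is N_r, the number of reads that contributed a prefix;
    reads that were too short or carried an N inside the prefix window are
    tallied in ``excluded_reads`` instead. Binding the table to a genome
    length L makes ``average_start_frequency`` (Freq_ave = N_r / (2 L))
    available.
    """

    prefix_length: int
    counts: dict[str, int]
    total_reads: int
    excluded_reads: int = 0
    genome_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.prefix_length < 1:
            raise ValueError("prefix_length must be >= 1")
        if sum(self.counts.values()) != self.total_reads:
            raise ValueError("sum of prefix counts must equal total_reads")
        if any(len(p) != self.prefix_length for p in self.counts):
            raise ValueError("every prefix key must have length prefix_length")

    def bind(self, genome_length: int) -> "StartFrequencyTable":
        """Attach the genome length L; returns self for chaining."""
        if genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        self.genome_length = genome_length
        return self

    @property
    def average_start_frequency(self) -> float:
        """Freq_ave = N_r / (2 L); requires a bound genome length."""
        if self.genome_length is None:
            raise ValueError("table is not bound to a genome length; call bind(L) first")
        return average_start_frequency(self.total_reads, self.genome_length)


@dataclass(frozen=True)
class RatioResult:
    """Terminal-to-average frequency ratio R = Freq_ter / Freq_ave."""

    terminal_frequency: int
    average_frequency: float
    ratio: float
    ratio_rounded: int


def count_start_prefixes(
    reads: Iterable[SequenceRead],
    prefix_length: int = DEFAULT_PREFIX_LENGTH,
) -> StartFrequencyTable:
    """Tally the first ``prefix_length`` bases of every read.

    Reads shorter than the prefix window, or with an N inside it, are
    excluded (the theory assumes exact read starts; an ambiguous base would
    fragment a terminal peak into spurious low-count prefixes).
    """
    if prefix_length < 1:
        raise ValueError("prefix_length must be >= 1")
    counts: dict[str, int] = {}
    total = 0
    excluded = 0
    for read in reads:
        prefix = read.bases[:prefix_length]
        if len(prefix) < prefix_length or "N" in prefix:
            excluded += 1
            continue
        counts[prefix] = counts.get(prefix, 0) + 1
        total += 1
    return StartFrequencyTable(
        prefix_length=prefix_length,
        counts=counts,
        total_reads=total,
        excluded_reads=excluded,
    )


def average_start_frequency(total_reads: int, genome_length: int) -> float:
    """Freq_ave = N_r / (2 L): expected read starts per position per strand."""
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    return total_reads / (2 * genome_length)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def terminal_ratio(terminal_frequency: int, average_frequency: float) -> RatioResult:
    """R = Freq_ter / Freq_ave, with nearest-integer (half away from zero) rounding."""
    if average_frequency <= 0:
        raise ValueError("average_frequency must be > 0")
    ratio = terminal_frequency / average_frequency
    return RatioResult(
        terminal_frequency=terminal_frequency,
        average_frequency=average_frequency,
        ratio=ratio,
        ratio_rounded=_round_half_away(ratio),
    )


def theoretical_ratio(mean_read_length: float) -> float:
    """The idealised peak-to-background ratio, R = 2 * L_reads."""
    if mean_read_length < 0:
        raise ValueError("mean_read_length must be >= 0")
    return 2.0 * mean_read_length


def rank_frequencies(table: StartFrequencyTable) -> list[tuple[str, int, int]]:
    """Rank prefixes by descending count.

    Ties share a 1-based dense rank and are ordered lexicographically, so
    the output is deterministic.
    """
    ordered = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked: list[tuple[str, int, int]] = []
    rank = 0
    previous: Optional[int] = None
    for prefix, count in ordered:
        if count != previous:
            rank += 1
            previous = count
        ranked.append((prefix, count, rank))
    return ranked


def frequency_histogram(
    table: StartFrequencyTable,
    bin_edges: Sequence[int],
) -> list[tuple[tuple[int, int], float]]:
    """Fraction of *reads* whose start-prefix count falls in each bin.

    Bins are half-open ``[edge_i, edge_{i+1})``. A prefix seen c times
    contributes c reads to the bin containing c. Fractions sum to <= 1; the
    remainder lies above the last edge.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])) or len(edges) < 2:
        raise ValueError("bin_edges must contain >= 2 strictly increasing values")
    mass = [0 for _ in range(len(edges) - 1)]
    for count in table.counts.values():
        for i in range(len(edges) - 1):
            if edges[i] <= count < edges[i + 1]:
                mass[i] += count
                break
    total = table.total_reads
    return [
        ((edges[i], edges[i + 1]), (mass[i] / total if total else 0.0))
        for i in range(len(edges) - 1)
    ]


def matched_percentage(matched_reads: int, total_reads: int) -> float:
    """Percentage of library reads that mapped to the assembly (0-100)."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not 0 <= matched_reads <= total_reads:
        raise ValueError("matched_reads must lie in [0, total_reads]")
    return 100.0 * matched_reads / total_reads


def write_ranked_tsv(
    table: StartFrequencyTable,
    path: PathLike,
    top: Optional[int] = None,
) -> None:
    """Export the ranked table as TSV (rank, prefix, count, ratio)."""
    freq_ave = table.average_start_frequency if table.genome_length is not None else None
    rows = rank_frequencies(table)
    if top is not None:
        rows = rows[:top]
    with open(path, "w") as handle:
        handle.write("rank\tprefix\tcount\tratio\n")
        for prefix, count, rank in rows:
            ratio = f"{count / freq_ave:.2f}" if freq_ave else "NA"
            handle.write(f"{rank}\t{prefix}\t{count}\t{ratio}\n")


def summary_dict(table: StartFrequencyTable, top_k: int = 10) -> dict:
    """JSON-ready summary: N_r, L, Freq_ave and the top-k ranked prefixes."""
    freq_ave = table.average_start_frequency if table.genome_length is not None else None
    return {
        "prefix_length": table.prefix_length,
        "total_reads": table.total_reads,
        "excluded_reads": table.excluded_reads,
        "genome_length": table.genome_length,
        "average_start_frequency": round(freq_ave, 2) if freq_ave is not None else None,
        "top": [
            {"rank": rank, "prefix": prefix, "count": count}
            for prefix, count, rank in rank_frequencies(table)[:top_k]
        ],
    }
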