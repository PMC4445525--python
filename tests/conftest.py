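"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from costerm import GenomeRecord, SequenceRead, reverse_complement, simulate_genome


def make_reads(sequences: list[str]) -> list[SequenceRead]:
    return [SequenceRead(f"r{i}", s) for i, s in enumerate(sequences)]


def brute_force_locate(prefix: str, genome: str) -> list[tuple[int, str]]:
    """Independent oracle for prefix mapping: scan every circular position
    on both strands by direct slice comparison."""
    L = len(genome)
    n = len(prefix)
    doubled = genome + genome
    hits = set()
    for s in range(L):
        window = doubled[s : s + n]
        if window == prefix:
            hits.add((s + 1, "positive"))
        if reverse_complement(window) == prefix:
            hits.add(((s + n - 1) % L + 1, "negative"))
    return sorted(hits)


@pytest.fixture
def small_genome() -> GenomeRecord:
    return simulate_genome(2000, seed=1234)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(entries: list[tuple[str, str]], name: str = "genome.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{h}\n{s}\n" for h, s in entries))
        return path

    return _write


@pytest.fixture
def fastq_file(tmp_path):
    def _write(reads: list[tuple[str, str, str]], name: str = "reads.fastq"):
        path = tmp_path / name
        path.write_text("".join(f"@{h}\n{s}\n+\n{q}\n" for h, s, q in reads))
        return path

    return _write
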