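"""End-to-end pipeline: reads + assembled genome -> termini report.

The report aggregates everything the analysis computes — read-set stats,
Freq_ave, per-strand terminus calls with ratios, the resolved gap geometry,
the classified end structure, the ranked high-frequency table and the
occurrence histogram — together with the full parameter record, so any
number in it can be recomputed from the inputs alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

from . import __version__
from .classify import (
    DEFAULT_K_MAX,
    DEFAULT_MIN_FLANK,
    EndStructure,
    classify_end_structure,
    find_junction_reads,
)
from .freqstats import (
    DEFAULT_PREFIX_LENGTH,
    count_start_prefixes,
    rank_frequencies,
    frequency_histogram,
)
from .seqcore import FormatError, GenomeRecord, PathLike, SequenceRead, read_fasta, read_reads
from .terminus import (
    DEFAULT_MIN_RATIO,
    EndGeometry,
    TerminusCall,
    build_circular_reference,
    call_termini,
    locate_prefix,
    resolve_geometry,
    terminus_positions_report,
)

__all__ = ["PipelineParams", "TerminiReport", "run_pipeline", "analyze", "render_report"]

DEFAULT_HISTOGRAM_EDGES = (0, 1, 2, 5, 10, 20, 50, 100, 200, 500, 1000)


@dataclass(frozen=True)
class PipelineParams:
    """Tunable analysis parameters with their documented defaults."""

    prefix_length: int = DEFAULT_PREFIX_LENGTH
    min_ratio: float = DEFAULT_MIN_RATIO
    k_max: int = DEFAULT_K_MAX
    min_flank: int = DEFAULT_MIN_FLANK
    top_k: int = 50
    histogram_edges: tuple[int, ...] = DEFAULT_HISTOGRAM_EDGES

    @property
    def extension_length(self) -> int:
        # covers any overhang up to k_max when mapping across the origin
        return self.prefix_length + self.k_max


@dataclass
class TerminiReport:
    """Complete, reproducible record of one termini analysis."""

    genome_id: str
    genome_length: int
    total_reads: int
    excluded_reads: int
    mean_read_length: float
    average_start_frequency: float
    positive_call: Optional[TerminusCall]
    negative_call: Optional[TerminusCall]
    geometry: Optional[EndGeometry]
    structure: Optional[EndStructure]
    top_table: list[dict]
    histogram: list[dict]
    parameters: dict
    version: str = __version__

    def to_dict(self) -> dict:
        def call_dict(call: Optional[TerminusCall]) -> Optional[dict]:
            if call is None:
                return None
            d = asdict(call)
            d["ratio"] = round(d["ratio"], 2)
            return d

        structure = None
        if self.structure is not None:
            five_prime, three_prime_last = terminus_positions_report(self.structure.geometry)
            evidence = self.structure.evidence
            structure = {
                "end_type": self.structure.end_type.value,
                "overhang_length": self.structure.overhang_length,
                "overhang_sequence": self.structure.overhang_sequence,
                "flagged": self.structure.flagged,
                "five_prime_start": five_prime,
                "three_prime_last_base": three_prime_last,
                "junction_evidence": None
                if evidence is None
                else {
                    "junction_read_count": evidence.junction_read_count,
                    "overhang_copies_observed": {
                        str(k): v for k, v in evidence.overhang_copies_observed.items()
                    },
                    "min_flank": evidence.min_flank,
                },
            }
        return {
            "genome_id": self.genome_id,
            "genome_length": self.genome_length,
            "total_reads": self.total_reads,
            "excluded_reads": self.excluded_reads,
            "mean_read_length": round(self.mean_read_length, 2),
            "average_start_frequency": round(self.average_start_frequency, 2),
            "positive_call": call_dict(self.positive_call),
            "negative_call": call_dict(self.negative_call),
            "gap": None if self.geometry is None else self.geometry.gap,
            "structure": structure,
            "top_table": self.top_table,
            "histogram": self.histogram,
            "parameters": self.parameters,
            "version": self.version,
        }


def analyze(
    genome: GenomeRecord,
    reads: list[SequenceRead],
    params: Optional[PipelineParams] = None,
) -> TerminiReport:
    """Run the full analysis on in-memory inputs."""
    params = params or PipelineParams()
    table = count_start_prefixes(reads, params.prefix_length).bind(genome.length)
    extension = min(params.extension_length, genome.length)
    reference = build_circular_reference(genome, extension)
    positive, negative = call_termini(table, reference, params.min_ratio)
    freq_ave = table.average_start_frequency

    geometry: Optional[EndGeometry] = None
    structure: Optional[EndStructure] = None
    if positive is not None and negative is not None:
        geometry = resolve_geometry(positive, negative, genome.length)
        evidence = find_junction_reads(
            reads, genome, geometry, params.min_flank, params.k_max
        )
        structure = classify_end_structure(geometry, evidence, params.k_max, genome)

    top_table = []
    for prefix, count, rank in rank_frequencies(table)[: params.top_k]:
        loci = locate_prefix(prefix, reference) if count / freq_ave >= 1 else []
        top_table.append(
            {
                "rank": rank,
                "prefix": prefix,
                "count": count,
                "ratio": round(count / freq_ave, 2) if freq_ave else None,
                "loci": [{"position": p, "strand": s} for p, s in loci[:5]],
            }
        )
    histogram = [
        {"bin_low": lo, "bin_high": hi, "read_fraction": round(frac, 6)}
        for (lo, hi), frac in frequency_histogram(table, list(params.histogram_edges))
    ]
    lengths = [len(r) for r in reads]
    mean_len = sum(lengths) / len(lengths) if lengths else 0.0
    return TerminiReport(
        genome_id=genome.identifier,
        genome_length=genome.length,
        total_reads=table.total_reads,
        excluded_reads=table.excluded_reads,
        mean_read_length=mean_len,
        average_start_frequency=freq_ave,
        positive_call=positive,
        negative_call=negative,
        geometry=geometry,
        structure=structure,
        top_table=top_table,
        histogram=histogram,
        parameters={
            "prefix_length": params.prefix_length,
            "min_ratio": params.min_ratio,
            "k_max": params.k_max,
            "min_flank": params.min_flank,
            "top_k": params.top_k,
            "histogram_edges": list(params.histogram_edges),
        },
    )


def run_pipeline(
    genome_path: PathLike,
    reads_path: PathLike,
    params: Optional[PipelineParams] = None,
) -> TerminiReport:
    """File-based entry point: FASTA genome + FASTQ/FASTA reads -> report.

    Deterministic given inputs and parameters. Reads are streamed once for
    counting and once more for junction evidence.
    """
    genomes = read_fasta(genome_path)
    if not genomes:
        raise FormatError(f"{genome_path}: no genome records found")
    genome = genomes[0]
    reads = list(read_reads(reads_path))
    return analyze(genome, reads, params)


def _text_block(report: TerminiReport) -> str:
    lines = [
        f"costerm {report.version} termini report",
        f"genome          {report.genome_id}  (L = {report.genome_length:,} bp)",
        f"reads counted   {report.total_reads:,}  (excluded {report.excluded_reads:,}; "
        f"mean length {report.mean_read_length:.1f} bp)",
        f"Freq_ave        {report.average_start_frequency:.2f}",
        "",
        "strand    Freq_ave  Freq_ter  ratio  terminal sequence",
    ]
    for call in (report.positive_call, report.negative_call):
        if call is None:
            continue
        lines.append(
            f"{call.strand:<8}  {report.average_start_frequency:>8.2f}  "
            f"{call.frequency:>8,}  {round(call.ratio):>5}  {call.prefix}"
        )
    if report.positive_call is None or report.negative_call is None:
        missing = [
            s
            for s, c in (
                ("positive", report.positive_call),
                ("negative", report.negative_call),
            )
            if c is None
        ]
        lines.append(f"no terminus detected on strand(s): {', '.join(missing)}")
    if report.structure is not None:
        s = report.to_dict()["structure"]
        lines += [
            "",
            f"end structure   {s['end_type']}  (overhang k = {s['overhang_length']} nt"
            + (f", sequence {s['overhang_sequence']}" if s["overhang_sequence"] else "")
            + ")",
            f"5' start        position {s['five_prime_start']:,}",
            f"3' last base    position {s['three_prime_last_base']:,}",
        ]
        ev = s["junction_evidence"]
        if ev is not None:
            lines.append(
                f"junction reads  {ev['junction_read_count']} "
                f"(overhang copies {ev['overhang_copies_observed']})"
            )
        if s["flagged"]:
            lines.append("WARNING: junction copy-number evidence contradicts the call")
    return "\n".join(lines) + "\n"


def _tsv_block(report: TerminiReport) -> str:
    out = ["rank\tprefix\tcount\tratio\tposition\tstrand"]
    for row in report.top_table:
        locus = row["loci"][0] if row["loci"] else {"position": "NA", "strand": "NA"}
        out.append(
            f"{row['rank']}\t{row['prefix']}\t{row['count']}\t{row['ratio']}"
            f"\t{locus['position']}\t{locus['strand']}"
        )
    return "\n".join(out) + "\n"


def render_report(report: TerminiReport, format: str = "json") -> str:
    """Render a report as ``json``, ``tsv`` (ranked table) or ``text``."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if format == "tsv":
        return _tsv_block(report)
    if format == "text":
        return _text_block(report)
    raise ValueError(f"unknown report format {format!r}; use json, tsv or text")
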