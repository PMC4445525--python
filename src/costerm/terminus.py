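"""Terminus calling on a circularized reference.

A linear phage genome circularizes through its terminal repetitions during
replication, so an assembler typically reports an arbitrary-origin circular
contig. To map read-start prefixes across the origin, the reference is
extended by its own first bases ("circularized"); exact matches on both
strands are then reduced modulo L back to genome coordinates.

Coordinate conventions (1-based, positive strand):

* ``a`` — position of the first base of the top-strand terminal read
  (the 5' terminus of the positive strand).
* ``b`` — positive-strand coordinate of the 5'-most base of the
  bottom-strand terminal read (the 5' terminus of the negative strand).
* ``g = (a - b - 1) mod L`` — the circular gap: the number of genome
  positions strictly between b and a going forward around the circle.
  For a 3'-protruding cohesive end of length k, end repair chews the
  overhang back, terminal reads start at a and b flanking it, and g = k.
  For a 5'-protruding end the fill-in reaction copies the overhang to both
  repaired ends and g = L - k. A blunt genome gives g = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .freqstats import StartFrequencyTable, rank_frequencies
from .seqcore import GenomeRecord, reverse_complement

__all__ = [
    "CircularReference",
    "TerminusCall",
    "EndGeometry",
    "AmbiguousTerminusError",
    "build_circular_reference",
    "circular_slice",
    "locate_prefix",
    "call_termini",
    "resolve_geometry",
    "extract_overhang",
    "terminus_positions_report",
    "DEFAULT_MIN_RATIO",
]

DEFAULT_MIN_RATIO = 50.0

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class CircularReference:
    """A genome extended by its own first ``extension_length`` bases."""

    source: GenomeRecord
    extension_length: int
    extended_sequence: str

    @property
    def genome_length(self) -> int:
        return self.source.length


@dataclass(frozen=True)
class TerminusCall:
    """One called terminus: the peak prefix, where it maps, and its ratio R."""

    strand: str
    prefix: str
    frequency: int
    position: int
    ratio: float


@dataclass(frozen=True)
class EndGeometry:
    """The two terminal start positions and the circular gap between them."""

    top_start: int  # a
    bottom_start: int  # b
    genome_length: int  # L
    gap: int  # g = (a - b - 1) mod L

    def __post_init__(self) -> None:
        L = self.genome_length
        if not (1 <= self.top_start <= L and 1 <= self.bottom_start <= L):
            raise ValueError("terminal positions must lie in [1, L]")
        if not 0 <= self.gap < L:
            raise ValueError("gap must lie in [0, L)")


class AmbiguousTerminusError(RuntimeError):
    """The top candidate prefix maps to more than one genomic locus."""

    def __init__(self, prefix: str, loci: list[tuple[int, str]]):
        self.prefix = prefix
        self.loci = loci
        super().__init__(
            f"top prefix {prefix!r} maps to {len(loci)} loci {loci}; "
            "an exact repeat breaks the single-terminus assumption"
        )


def build_circular_reference(genome: GenomeRecord, extension_length: int) -> CircularReference:
    """Append the genome's first ``extension_length`` bases to its end."""
    if not 0 <= extension_length <= genome.length:
        raise ValueError(
            f"extension_length must lie in [0, L={genome.length}], got {extension_length}"
        )
    extended = genome.sequence + genome.sequence[:extension_length]
    return CircularReference(genome, extension_length, extended)


def circular_slice(sequence: str, start: int, length: int) -> str:
    """1-based circular substring: positions start .. start+length-1 mod L."""
    L = len(sequence)
    if length < 0:
        raise ValueError("length must be >= 0")
    if length > L:
        raise ValueError("cannot take a circular slice longer than the sequence")
    i = (start - 1) % L
    if i + length <= L:
        return sequence[i : i + length]
    return sequence[i:] + sequence[: i + length - L]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def locate_prefix(prefix: str, reference: CircularReference) -> list[tuple[int, str]]:
    """Exact occurrences of ``prefix`` on both strands of the circular genome.

    Positions are the 1-based positive-strand coordinate of the occurrence's
    5'-most base *on its own strand*: for a negative-strand hit covering
    positive positions p..p+n-1 that is p+n-1 (the read extends leftward).
    Results are deduplicated modulo L and sorted.
    """
    if len(prefix) > reference.extension_length:
        raise ValueError(
            f"prefix length {len(prefix)} exceeds reference extension "
            f"{reference.extension_length}; circular occurrences could be missed"
        )
    L = reference.genome_length
    ext = reference.extended_sequence
    n = len(prefix)
    hits: set[tuple[int, str]] = set()
    for i in _find_all(ext, prefix):
        if i < L:
            hits.add((i + 1, POSITIVE))
    for i in _find_all(ext, reverse_complement(prefix)):
        if i < L:
            hits.add(((i + n - 1) % L + 1, NEGATIVE))
    return sorted(hits)


def call_termini(
    table: StartFrequencyTable,
    reference: CircularReference,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> tuple[Optional[TerminusCall], Optional[TerminusCall]]:
    """Call at most one terminus per strand from the ranked prefix table.

    Walks prefixes in descending count order while their ratio R stays at or
    above ``min_ratio``. The first prefix mapping to a single locus on a
    not-yet-called strand becomes that strand's terminus. A candidate that
    maps to multiple loci while a strand is still uncalled raises
    :class:`AmbiguousTerminusError` (an exact genomic repeat genuinely
    breaks the method). Unmapped prefixes (e.g. sequencing errors) are
    skipped. A strand with no peak reaching ``min_ratio`` yields ``None``.
    """
    if table.genome_length is None:
        table.bind(reference.genome_length)
    elif table.genome_length != reference.genome_length:
        raise ValueError("table is bound to a different genome length than the reference")
    freq_ave = table.average_start_frequency
    calls: dict[str, Optional[TerminusCall]] = {POSITIVE: None, NEGATIVE: None}
    if freq_ave == 0:
        return calls[POSITIVE], calls[NEGATIVE]
    for prefix, count, _rank in rank_frequencies(table):
        ratio = count / freq_ave
        if ratio < min_ratio:
            break
        if calls[POSITIVE] is not None and calls[NEGATIVE] is not None:
            break
        loci = locate_prefix(prefix, reference)
        if not loci:
            continue
        if len(loci) > 1:
            if any(calls[strand] is None for _pos, strand in loci):
                raise AmbiguousTerminusError(prefix, loci)
            continue
        position, strand = loci[0]
        if calls[strand] is None:
            calls[strand] = TerminusCall(
                strand=strand, prefix=prefix, frequency=count, position=position, ratio=ratio
            )
    return calls[POSITIVE], calls[NEGATIVE]


def _position(call: Union[TerminusCall, int]) -> int:
    return call.position if isinstance(call, TerminusCall) else int(call)


def resolve_geometry(
    top: Union[TerminusCall, int],
    bottom: Union[TerminusCall, int],
    genome_length: int,
) -> EndGeometry:
    """Circular gap between the two termini: g = (a - b - 1) mod L.

    ``top``/``bottom`` may be calls or bare 1-based positions. The gap is
    rotation-invariant: rotating the assembly shifts a and b together and
    leaves g unchanged.
    """
    if isinstance(top, TerminusCall) and top.strand != POSITIVE:
        raise ValueError("top call must be on the positive strand")
    if isinstance(bottom, TerminusCall) and bottom.strand != NEGATIVE:
        raise ValueError("bottom call must be on the negative strand")
    a = _position(top)
    b = _position(bottom)
    g = (a - b - 1) % genome_length
    return EndGeometry(top_start=a, bottom_start=b, genome_length=genome_length, gap=g)


def extract_overhang(genome: GenomeRecord, geometry: EndGeometry, end_type: str) -> str:
    """Positive-strand sequence of the single-stranded cohesive end.

    For a 3'-protruding end the overhang is the g bases strictly between the
    two terminal starts (circular positions b+1 .. b+g). For a 5'-protruding
    end of length k = L - g it is positions a .. a+k-1. Blunt ends have no
    overhang.
    """
    if geometry.genome_length != genome.length:
        raise ValueError("geometry genome_length does not match the genome")
    seq = genome.sequence
    if end_type == "3prime":
        return circular_slice(seq, geometry.bottom_start + 1, geometry.gap)
    if end_type == "5prime":
        return circular_slice(seq, geometry.top_start, genome.length - geometry.gap)
    if end_type == "blunt":
        return ""
    raise ValueError(f"end_type must be '3prime', '5prime' or 'blunt', got {end_type!r}")


def terminus_positions_report(geometry: EndGeometry) -> tuple[int, int]:
    """(5' start, last paired base of the 3' terminus), 1-based.

    For a 3'-protruding genome assembled with a = 1 the second value equals
    L - g, e.g. a 40,713 bp genome with a 9-nt overhang ends its paired
    region at position 40,704.
    """
    return geometry.top_start, geometry.bottom_start
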