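"""End-structure classification from gap geometry and junction reads.

The decisive signal is structural, driven by library-prep end repair:

* Blunt termini ligate/assemble with nothing between them: g = 0.
* A 3'-protruding cohesive end is removed by the polymerase's 3'->5'
  exonuclease before adapter ligation, so the overhang is *absent* from
  terminal reads and appears only as a g = k gap between the two terminal
  start positions.
* A 5'-protruding end is filled in (5'->3' synthesis), duplicating the
  overhang onto both repaired ends; the terminal starts then overlap by k
  and g = L - k.

Rare reads spanning the joined ends of circularized replication
intermediates corroborate the call: a genuine circular intermediate carries
the overhang exactly once at the junction, whereas a blunt-ligation chimera
of two repaired 3'-chewed ends would carry zero copies, and a chimera of
two filled-in 5' ends two copies. Junction reads are counted as evidence,
never used as the primary classifier — they are orders of magnitude rarer
than terminal reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .seqcore import GenomeRecord, SequenceRead, _COMPLEMENT
from .terminus import EndGeometry, circular_slice, extract_overhang

__all__ = [
    "EndType",
    "JunctionEvidence",
    "EndStructure",
    "find_junction_reads",
    "classify_end_structure",
    "DEFAULT_K_MAX",
    "DEFAULT_MIN_FLANK",
]

DEFAULT_K_MAX = 200
DEFAULT_MIN_FLANK = 10


class EndType(str, Enum):
    COS_3_PRIME = "cos_3prime"
    COS_5_PRIME = "cos_5prime"
    BLUNT = "blunt"
    UNCLASSIFIED = "unclassified"


@dataclass
class JunctionEvidence:
    """Reads spanning the circular junction, tallied by overhang copy number."""

    junction_read_count: int
    overhang_copies_observed: dict[int, int]
    min_flank: int

    def __post_init__(self) -> None:
        if self.junction_read_count < 0:
            raise ValueError("junction_read_count must be >= 0")
        if sum(self.overhang_copies_observed.values()) != self.junction_read_count:
            raise ValueError("copy-number tallies must sum to junction_read_count")


@dataclass
class EndStructure:
    """The classified terminus structure of a linear dsDNA genome."""

    end_type: EndType
    overhang_length: int  # k
    overhang_sequence: str  # positive-strand representation
    geometry: EndGeometry
    evidence: Optional[JunctionEvidence] = None
    flagged: bool = False  # junction copy-number evidence contradicts the call

    def __post_init__(self) -> None:
        g, L = self.geometry.gap, self.geometry.genome_length
        if self.end_type is EndType.BLUNT:
            if self.overhang_length != 0 or self.overhang_sequence:
                raise ValueError("blunt ends must have no overhang")
        elif self.end_type is EndType.COS_3_PRIME:
            if self.overhang_length != g:
                raise ValueError("3'-protruding overhang length must equal the gap g")
        elif self.end_type is EndType.COS_5_PRIME:
            if self.overhang_length != L - g:
                raise ValueError("5'-protruding overhang length must equal L - g")
        if self.overhang_sequence and len(self.overhang_sequence) != self.overhang_length:
            raise ValueError("overhang_sequence length must equal overhang_length")


def _candidate(geometry: EndGeometry, k_max: int) -> tuple[EndType, int]:
    """Map the gap to a tentative end type and overhang length k."""
    g, L = geometry.gap, geometry.genome_length
    if g == 0:
        return EndType.BLUNT, 0
    if 1 <= g <= k_max:
        return EndType.COS_3_PRIME, g
    if g >= L - k_max:
        return EndType.COS_5_PRIME, L - g
    return EndType.UNCLASSIFIED, 0


def _junction_patterns(
    genome: GenomeRecord, geometry: EndGeometry, end_type: EndType, k: int, flank: int
) -> tuple[str, list[str]]:
    """(overhang, patterns for 0/1/2 overhang copies) around the junction.

    The junction is where the genome's two ends meet in the circular form.
    Each pattern is ``left flank + c copies of overhang + right flank`` with
    ``flank`` paired bases on each side.
    """
    seq = genome.sequence
    a, b, L = geometry.top_start, geometry.bottom_start, geometry.genome_length
    if end_type is EndType.COS_5_PRIME:
        overhang = circular_slice(seq, a, k)
        left = circular_slice(seq, a - flank, flank)
        right = circular_slice(seq, a + k, flank)
    else:  # blunt or 3'-protruding: overhang sits strictly between b and a
        overhang = circular_slice(seq, b + 1, geometry.gap) if end_type is EndType.COS_3_PRIME else ""
        left = circular_slice(seq, b - flank + 1, flank)
        right = circular_slice(seq, a, flank)
    if overhang:
        patterns = [left + overhang * c + right for c in (0, 1, 2)]
    else:
        patterns = [left + right]
    return overhang, patterns


def find_junction_reads(
    reads: Iterable[SequenceRead],
    genome: GenomeRecord,
    geometry: EndGeometry,
    min_flank: int = DEFAULT_MIN_FLANK,
    k_max: int = DEFAULT_K_MAX,
) -> JunctionEvidence:
    """Count reads that span the circular junction, in either orientation.

    A read is counted when it contains, exactly, ``min_flank`` paired bases
    from each side of the junction with 0, 1 or 2 copies of the candidate
    overhang between them; the copy number is tallied (highest copy number
    wins when patterns nest). With a mid-range gap (no plausible cohesive
    end) there is no candidate junction and the evidence is empty.
    """
    if min_flank < 5:
        raise ValueError("min_flank < 5 would admit spurious matches")
    end_type, k = _candidate(geometry, k_max)
    if end_type is EndType.UNCLASSIFIED:
        return JunctionEvidence(0, {}, min_flank)
    overhang, patterns = _junction_patterns(genome, geometry, end_type, k, min_flank)
    copies = {c: 0 for c in ((0, 1, 2) if overhang else (0,))}
    count = 0
    order = list(reversed(range(len(patterns))))  # prefer the highest copy number
    for read in reads:
        bases = read.bases
        rc: Optional[str] = None
        for c in order:
            pattern = patterns[c]
            if pattern in bases:
                hit = True
            else:
                if rc is None:
                    rc = bases.translate(_COMPLEMENT)[::-1]
                hit = pattern in rc
            if hit:
                copies[c] += 1
                count += 1
                break
    return JunctionEvidence(count, copies, min_flank)


def classify_end_structure(
    geometry: EndGeometry,
    evidence: Optional[JunctionEvidence] = None,
    k_max: int = DEFAULT_K_MAX,
    genome: Optional[GenomeRecord] = None,
) -> EndStructure:
    """Classify the end structure from the circular gap g.

    g = 0 -> blunt; 1 <= g <= k_max -> 3'-protruding with k = g;
    g >= L - k_max -> 5'-protruding with k = L - g; anything in between
    (a repeat artifact or misassembly, not a credible cohesive end) is
    UNCLASSIFIED. When a genome is supplied the overhang sequence is
    extracted; when junction evidence is supplied it is consistency-checked:
    a 3'-protruding call expects circular intermediates carrying exactly one
    overhang copy, so a majority at two copies flags the call.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    end_type, k = _candidate(geometry, k_max)
    if genome is not None and end_type in (EndType.COS_3_PRIME, EndType.COS_5_PRIME):
        type_str = "3prime" if end_type is EndType.COS_3_PRIME else "5prime"
        overhang_sequence = extract_overhang(genome, geometry, type_str)
    else:
        overhang_sequence = ""
    flagged = False
    if (
        evidence is not None
        and end_type is EndType.COS_3_PRIME
        and evidence.junction_read_count > 0
        and evidence.overhang_copies_observed.get(2, 0) > evidence.junction_read_count / 2
    ):
        flagged = True
    return EndStructure(
        end_type=end_type,
        overhang_length=k,
        overhang_sequence=overhang_sequence,
        geometry=geometry,
        evidence=evidence,
        flagged=flagged,
    )
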