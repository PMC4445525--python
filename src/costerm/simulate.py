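"""Generative model of cos-phage packaging, library prep and sequencing.

The model follows the life cycle that produces the read-start signal:

1. Replication yields concatemers; the terminase cuts each genome unit out
   with staggered nicks, leaving blunt, 3'-protruding or 5'-protruding
   cohesive ends of length k.
2. Library end repair blunts every molecule: 3' overhangs are chewed back
   by the polymerase's 3'->5' exonuclease (the overhang disappears from the
   sequenced molecule), 5' overhangs are filled in (the overhang is copied
   onto both ends).
3. Molecules are fragmented and read 5'->3' from a strand; a small fraction
   of molecules are circularized replication intermediates whose fragments
   can span the end-to-end junction, carrying the overhang exactly once.

Two fragmentation modes are provided:

* ``theorem`` mode literalizes the idealisation behind the frequency-ratio
  result R = 2 * L_reads: every repaired molecule is tiled into consecutive
  read-length fragments, the leftmost read always starts at the top-strand
  terminus and the rightmost at the bottom-strand terminus, so the terminal
  start count is exactly m per terminus, and interior fragments are read
  from a uniformly chosen strand.
* ``realistic`` mode shears each molecule at random (geometric fragment
  lengths), optionally applies a size-selection window, and reads the first
  ``read_length`` bases of a random strand of each kept fragment. Both the
  random strand choice at terminal fragments and fragment-scale start
  spacing push the measured ratio below the idealised 2 * L_reads, the
  direction of bias seen in real libraries.

The planted truth always places the top terminus at a = 1; the bottom
terminus b and gap g follow from the end type (g = k for 3', L - k for 5',
0 for blunt).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .seqcore import (
    GenomeRecord,
    PathLike,
    SequenceRead,
    _COMPLEMENT,
    write_fasta,
    write_fastq,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genome",
    "make_mature_molecule",
    "simulate_reads",
    "run_simulation",
    "write_simulation",
]

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

END_TYPES = ("blunt", "3prime", "5prime")
MODES = ("theorem", "realistic")


def _rc(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the packaging + library model.

    ``molecule_count`` is m, the number of packaged genome copies;
    ``read_length`` is L_reads (fixed in theorem mode, a cap in realistic
    mode); ``mean_fragment_length`` sets the shearing scale in realistic
    mode (300 bp, the usual selected library size); ``size_selection`` is an
    optional (min, max) fragment-length window; ``intermediate_fraction`` is
    the fraction of molecules that are circularized replication
    intermediates contributing junction-spanning reads.
    """

    genome_length: int
    end_type: str = "3prime"
    overhang_length: int = 9
    molecule_count: int = 200
    read_length: int = 150
    mode: str = "theorem"
    intermediate_fraction: float = 0.001
    substitution_error_rate: float = 0.0
    size_selection: Optional[tuple[int, int]] = None
    mean_fragment_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_type not in END_TYPES:
            raise ValueError(f"end_type must be one of {END_TYPES}, got {self.end_type!r}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if (self.overhang_length == 0) != (self.end_type == "blunt"):
            raise ValueError("overhang_length must be 0 exactly for blunt ends")
        if self.overhang_length < 0 or self.overhang_length >= self.genome_length:
            raise ValueError("overhang_length must lie in [0, genome_length)")
        if self.genome_length < 1 or self.molecule_count < 1:
            raise ValueError("genome_length and molecule_count must be >= 1")
        if self.read_length < 1 or self.read_length > self.genome_length:
            raise ValueError("read_length must lie in [1, genome_length]")
        for name in ("intermediate_fraction", "substitution_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.size_selection is not None:
            lo, hi = self.size_selection
            if not 1 <= lo <= hi:
                raise ValueError("size_selection must be (min, max) with 1 <= min <= max")
        if self.mean_fragment_length < 1:
            raise ValueError("mean_fragment_length must be >= 1")


@dataclass
class SimulationTruth:
    """Planted ground truth; read origins are also encoded in read ids."""

    genome_id: str
    genome_length: int
    end_type: str
    overhang_length: int
    overhang_sequence: str
    top_terminus_position: int  # a
    bottom_terminus_position: int  # b
    molecule_count: int
    origin_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: PathLike) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path: PathLike) -> "SimulationTruth":
        with open(path) as handle:
            return cls(**json.load(handle))


def simulate_genome(length: int, seed: int) -> GenomeRecord:
    """Uniform random DNA of the given length, reproducible under the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seq = _BASE_LUT[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    return GenomeRecord(f"sim_genome_L{length}_s{seed}", seq)


def _planted_geometry(L: int, end_type: str, k: int) -> tuple[int, int, str]:
    """(a, b, overhang sequence slice spec) for a genome planted at a = 1."""
    if end_type == "3prime":
        return 1, L - k, "tail"  # overhang = positions L-k+1 .. L
    if end_type == "5prime":
        return 1, k, "head"  # overhang = positions 1 .. k
    return 1, L, "none"


def make_mature_molecule(genome: GenomeRecord, config: SimulationConfig) -> tuple[str, int, int]:
    """The end-repaired (blunted) duplex, as its top strand, plus (a, b).

    * blunt: the genome itself, length L; b = L.
    * 3'-protruding (k): the overhang is chewed back from both ends, leaving
      positions a..b with b = L - k; length L - k.
    * 5'-protruding (k): fill-in copies the overhang to both ends, giving
      genome + first k bases; length L + k; b = k.
    """
    if config.overhang_length >= genome.length:
        raise ValueError("overhang_length must be smaller than the genome")
    L, k = genome.length, config.overhang_length
    seq = genome.sequence
    a, b, where = _planted_geometry(L, config.end_type, k)
    if where == "tail":
        return seq[: L - k], a, b
    if where == "head":
        return seq + seq[:k], a, b
    return seq, a, b


def _overhang_sequence(genome: GenomeRecord, config: SimulationConfig) -> str:
    L, k = genome.length, config.overhang_length
    if config.end_type == "3prime":
        return genome.sequence[L - k :]
    if config.end_type == "5prime":
        return genome.sequence[:k]
    return ""


def _apply_errors(bases: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(bases), rate)
    if n_err == 0:
        return bases
    positions = rng.choice(len(bases), size=n_err, replace=False)
    out = list(bases)
    alphabet = "ACGT"
    for p in positions:
        current = out[p]
        choices = [c for c in alphabet if c != current]
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _shear(length: int, rng: np.random.Generator, mean_fragment: int) -> list[tuple[int, int]]:
    """Random shearing: successive geometric fragment lengths covering [0, length)."""
    bounds = []
    s = 0
    while s < length:
        frag = int(rng.geometric(1.0 / mean_fragment))
        e = min(s + frag, length)
        bounds.append((s, e))
        s = e
    return bounds


def simulate_reads(
    genome: GenomeRecord, config: SimulationConfig
) -> tuple[list[SequenceRead], SimulationTruth]:
    """Generate the read set and its ground truth for one library.

    Reads carry their origin (terminal/internal/junction) in the identifier
    suffix; the truth object tallies origins and records the planted
    geometry. Identical (genome, config) pairs give identical output.
    """
    if config.genome_length != genome.length:
        raise ValueError("config.genome_length must equal the genome's length")
    L = genome.length
    Lr = config.read_length
    rng = np.random.default_rng([config.seed, 1])
    # errors draw from their own stream so that fragmentation and strand
    # choices are identical with and without an error model
    err_rng = np.random.default_rng([config.seed, 2])
    duplex, a, b = make_mature_molecule(genome, config)
    n_intermediate = int(math.floor(config.intermediate_fraction * config.molecule_count + 0.5))
    n_linear = config.molecule_count - n_intermediate
    err = config.substitution_error_rate
    theorem = config.mode == "theorem"

    reads: list[SequenceRead] = []
    origin_counts = {"terminal": 0, "internal": 0, "junction": 0}

    def emit(bases: str, origin: str) -> None:
        if err > 0:
            bases = _apply_errors(bases, err, err_rng)
        origin_counts[origin] += 1
        reads.append(SequenceRead(f"sim_{len(reads):08d}_{origin}", bases))

    # --- linear (mature, repaired) molecules -------------------------------
    D = len(duplex)
    duplex_rc = _rc(duplex)
    if theorem:
        tile = [(s, min(s + Lr, D)) for s in range(0, D, Lr)]
        last = len(tile) - 1
        # Both terminal reads are full length and anchored exactly at their
        # terminus; the remainder of the tiling would otherwise leave the
        # bottom-strand terminal read as a short tail fragment.
        bottom_read = duplex_rc[: min(Lr, D)]
        for _ in range(n_linear):
            strands = rng.integers(0, 2, size=len(tile))
            for j, (s, e) in enumerate(tile):
                if j == 0:
                    emit(duplex[s:e], "terminal")
                elif j == last:
                    emit(bottom_read, "terminal")
                else:
                    emit(duplex[s:e] if strands[j] else _rc(duplex[s:e]), "internal")
    else:
        lo, hi = config.size_selection if config.size_selection else (1, D)
        for _ in range(n_linear):
            for s, e in _shear(D, rng, config.mean_fragment_length):
                if not lo <= e - s <= hi:
                    continue
                top = bool(rng.integers(0, 2))
                frag = duplex[s:e] if top else duplex_rc[D - e : D - s]
                origin = "terminal" if (s == 0 and top) or (e == D and not top) else "internal"
                emit(frag[:Lr], origin)

    # --- circularized intermediates ---------------------------------------
    # The circular form is the full genome (the overhang sequence appears
    # exactly once); fragments spanning the end-to-end junction are labelled.
    seq = genome.sequence
    for _ in range(n_intermediate):
        rot = int(rng.integers(0, L))
        circ = seq[rot:] + seq[:rot]
        j = (L - rot) % L  # junction sits between circ[j-1] and circ[j]
        if theorem:
            bounds = [(s, min(s + Lr, L)) for s in range(0, L, Lr)]
        else:
            lo, hi = config.size_selection if config.size_selection else (1, L)
            bounds = [(s, e) for s, e in _shear(L, rng, config.mean_fragment_length) if lo <= e - s <= hi]
        circ_rc = _rc(circ)
        for s, e in bounds:
            top = bool(rng.integers(0, 2))
            frag = circ[s:e] if top else circ_rc[L - e : L - s]
            origin = "junction" if s < j < e else "internal"
            emit(frag[:Lr], origin)

    truth = SimulationTruth(
        genome_id=genome.identifier,
        genome_length=L,
        end_type=config.end_type,
        overhang_length=config.overhang_length,
        overhang_sequence=_overhang_sequence(genome, config),
        top_terminus_position=a,
        bottom_terminus_position=b,
        molecule_count=config.molecule_count,
        origin_counts=origin_counts,
    )
    return reads, truth


def run_simulation(
    config: SimulationConfig, genome: Optional[GenomeRecord] = None
) -> tuple[GenomeRecord, list[SequenceRead], SimulationTruth]:
    """Draw a genome (unless given) and simulate a library from it."""
    if genome is None:
        genome = simulate_genome(config.genome_length, config.seed)
    reads, truth = simulate_reads(genome, config)
    return genome, reads, truth


def write_simulation(
    config: SimulationConfig,
    out_dir: PathLike,
    genome: Optional[GenomeRecord] = None,
) -> dict[str, Path]:
    """Run a simulation and write genome.fasta, reads.fastq and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, reads, truth = run_simulation(config, genome)
    paths = {
        "genome": out / "genome.fasta",
        "reads": out / "reads.fastq",
        "truth": out / "truth.json",
    }
    write_fasta([genome], paths["genome"])
    write_fastq(reads, paths["reads"])
    truth.to_json(paths["truth"])
    return paths
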