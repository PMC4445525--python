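# Methods

## Model

A linear dsDNA phage genome of length L is replicated as concatemers and
cut into unit-length genomes by the terminase. Depending on where the two
nicks fall, the mature molecule ends are blunt, 3′-protruding or
5′-protruding by k nt; the two single-stranded extensions are complementary
(cohesive). During Illumina/Ion-style library preparation every molecule is
end-repaired: a 3′ overhang is removed by the polymerase's 3′→5′
exonuclease, a 5′ overhang is filled in by 5′→3′ synthesis. Sequencing then
reads each fragment 5′→3′ from one strand.

Three consequences drive the method:

1. **Terminal read starts are over-represented.** With m packaged copies,
   each terminus starts exactly one read per molecule (Freq_ter = m),
   while an average position on one strand starts Freq_ave = N_r / (2L)
   reads. The expected peak-to-background ratio is
   R = Freq_ter / Freq_ave = 2 m L / N_r = 2 L_reads.
2. **End repair encodes the end type in the gap.** Map the two peak
   read-start 20-mers (one per strand) to a circularized reference and let
   a and b be the top- and bottom-strand terminal start positions
   (bottom reported as the positive-strand coordinate of its 5′ base).
   The circular gap g = (a − b − 1) mod L is 0 for blunt ends, k for a
   chewed-back 3′ overhang, and L − k for a filled-in 5′ overhang.
3. **Circular intermediates leave junction reads.** The genome circularizes
   through its cohesive ends during replication; reads spanning the joint
   contain flanking paired sequence on both sides with exactly one copy of
   the overhang between them. They are rare (a handful against terminal
   peaks in the thousands) and are used only to corroborate the call:
   a majority of junction reads carrying two overhang copies (the signature
   of blunt ligation between two filled-in ends) flags a 3′ call.

## Analysis procedure

1. Count the first `prefix_length` (default 20) bases of every read.
   Reads shorter than the window or with an N inside it are excluded and
   tallied; the theory assumes exact 5′ starts and an ambiguous base would
   fragment a peak. Freq_ave uses the counted reads, not the raw library
   size.
2. Extend the assembly by its own first `prefix_length + k_max` bases and
   find exact occurrences of candidate prefixes on both strands, reduced
   modulo L. Exact matching replaces similarity-threshold read mapping
   deliberately: termini are defined by exact start positions, and an
   approximate mapper adds parameters without changing the statistic.
3. Walk prefixes in descending count while R ≥ `min_ratio` (default 50).
   The first prefix mapping to a single locus on an uncalled strand becomes
   that strand's terminus. A multi-locus top candidate is a hard error —
   an exact repeat at the terminus genuinely breaks the method — and a
   strand with no qualifying peak is reported as "no terminus" (the
   expected outcome for headful/pac phages with circularly permuted
   genomes, which this tool deliberately does not attempt to call).
4. Resolve g and classify: g = 0 → blunt; 1 ≤ g ≤ `k_max` → 3′-protruding,
   k = g; g ≥ L − `k_max` → 5′-protruding, k = L − g; anything mid-range →
   unclassified (more plausibly a misassembly or repeat artifact than a
   multi-kilobase cohesive end). The overhang sequence is the circular
   slice b+1..b+g (3′) or a..a+k−1 (5′), reported on the positive strand.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `prefix_length` | 20 | nt | long enough to be unique in a ~40 kb genome (random collision ~L/4^20), short enough that every read covers it |
| `min_ratio` | 50 | — | observed practical ratios are ~200–350 against theoretical 2·L_reads of several hundred; library selection attenuates but not by an order of magnitude; 50 clears the ≤ ~2× Freq_ave background with margin |
| `k_max` | 200 | nt | known cos overhangs are ≤ ~20 nt; 200 leaves headroom while keeping mid-range gaps unclassified |
| `min_flank` | 10 | nt | junction patterns are ≥ 2×10+k nt, long enough that chance matches are negligible; < 5 is rejected |
| extension length | `prefix_length + k_max` | nt | any circular start position within the overhang region remains matchable |

Rounding conventions: ratios are rounded to the nearest integer, half away
from zero, and Freq_ave is displayed to 2 decimals. Published tables of
this statistic are not always internally consistent about ratio rounding
(floor in one row, nearest in another); one convention is fixed here.
Ranking uses dense ranks with lexicographic tie-break for determinism.

## The simulator

`costerm.simulate` generates a uniform-random genome, plants the terminus
at a = 1 with the configured end type and overhang length, applies the end
repair described above (chew-back / fill-in / identity), and emits reads
in one of two modes:

* **theorem** mode literalizes the idealisation behind R = 2·L_reads:
  every repaired molecule is tiled into consecutive read-length fragments;
  the leftmost read is always taken from the top strand (starting exactly
  at a) and the rightmost from the bottom strand (starting exactly at b),
  so Freq_ter = m holds exactly; interior fragments are read from a
  uniformly chosen strand. Read starts therefore sit on a lattice — ideal
  for exact self-checks, not a model of shearing.
* **realistic** mode shears each molecule into geometric-length fragments
  (`mean_fragment_length`, default 300 bp, the usual selected library
  size), optionally applies a size-selection window, and reads the first
  `read_length` bases of a uniformly chosen strand of each kept fragment.
  Terminal starts are halved by the strand choice and thinned by
  selection, so the measured R falls below 2·L_reads — the direction of
  bias real protocols show.

A configured fraction of molecules (default 0.001) are circularized
intermediates: the full circular genome, random rotation, sheared/tiled
like the rest; reads spanning the origin are labelled `junction`. The
number of intermediate molecules is floor(m·fraction + 0.5) so seeded runs
are reproducible. Substitution errors (default 0) are applied from a
dedicated RNG stream so that fragmentation is identical with and without
errors. Read origins (terminal/internal/junction) are encoded in read
identifiers and tallied in the truth object.

What the simulator does **not** emulate: Ion Torrent homopolymer indel
errors (the dominant real error mode), amplification/GC bias, paired-end
reads, quality-score variation, host DNA contamination, and chimeric
library artifacts. Passing tests therefore demonstrate correctness of the
statistics and the geometry under clean single-end reads with exact
starts; on real data the peaks are attenuated (hence `min_ratio` well
below the theoretical R) but the arithmetic is unchanged.

## Numerical and design choices

* Coordinates are 1-based inclusive on the positive strand everywhere;
  negative-strand features are reported by the positive-strand coordinate
  of their 5′ base, which makes g computable in one coordinate system.
* g is computed modulo L, so calls are invariant under rotation of the
  assembled circle (property-tested).
* Degenerate inputs: an empty read set yields a table with N_r = 0 and no
  calls (not an error); an absent prefix maps to an empty locus list; an
  unclassifiable gap is a value, not an error.
* FASTQ quality is parsed and length-checked but otherwise ignored; the
  simulator writes constant quality "I".
* The acceptance script's simulation (40 kb, m = 500, 150 bp reads,
  theorem mode) is sized to run in seconds while keeping the terminal
  peaks hundreds of standard deviations above background; test-suite
  simulations use 10–20 kb genomes and 50–5,000 molecules for the same
  reason.

## Known limitations

* Direct terminal repeats (DTRs), headful packaging and other non-cos
  packaging chemistries are out of scope; the tool reports "no terminus"
  rather than guessing.
* An exact repeat of the terminal 20-mer elsewhere in the genome is a hard
  ambiguity error by design.
* The junction copy-number check cannot distinguish biological circular
  intermediates from rare library chimeras that happen to reconstruct the
  junction; copy number is recorded without asserting origin.
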