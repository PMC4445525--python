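"""Circular reference mapping, terminus calling and gap geometry."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import numpy as np

from costerm import (
    AmbiguousTerminusError,
    EndGeometry,
    GenomeRecord,
    SimulationConfig,
    build_circular_reference,
    call_termini,
    count_start_prefixes,
    extract_overhang,
    locate_prefix,
    resolve_geometry,
    reverse_complement,
    run_simulation,
    simulate_genome,
    terminus_positions_report,
)
from costerm.terminus import circular_slice
from tests.conftest import brute_force_locate, make_reads


class TestCircularReference:
    def test_extension_concatenates_prefix(self):
        ref = build_circular_reference(GenomeRecord("g", "ACGTACGT"), 3)
        assert ref.extended_sequence == "ACGTACGTACG"

    def test_zero_extension(self, small_genome):
        ref = build_circular_reference(small_genome, 0)
        assert ref.extended_sequence == small_genome.sequence

    def test_extension_bound(self, small_genome):
        with pytest.raises(ValueError):
            build_circular_reference(small_genome, small_genome.length + 1)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 50), st.integers(60, 200))
    def test_length_by_construction(self, ext, length):
        genome = simulate_genome(length, seed=1)
        ref = build_circular_reference(genome, ext)
        assert len(ref.extended_sequence) == length + ext


class TestLocatePrefix:
    def test_genome_start_maps_to_position_one(self, small_genome):
        ref = build_circular_reference(small_genome, 100)
        assert locate_prefix(small_genome.sequence[:20], ref) == [(1, "positive")]

    def test_absent_prefix(self, small_genome):
        ref = build_circular_reference(small_genome, 100)
        assert locate_prefix("A" * 30, ref) == []

    def test_negative_strand_coordinate_is_five_prime_base(self, small_genome):
        p = 501  # 1-based; prefix covers positions 501..520 on the negative strand
        prefix = reverse_complement(small_genome.sequence[p - 1 : p + 19])
        ref = build_circular_reference(small_genome, 100)
        assert locate_prefix(prefix, ref) == [(p + 19, "negative")]

    def test_occurrence_across_origin(self, small_genome):
        L = small_genome.length
        prefix = circular_slice(small_genome.sequence, L - 5, 20)
        ref = build_circular_reference(small_genome, 100)
        assert (L - 5, "positive") in locate_prefix(prefix, ref)

    def test_prefix_longer_than_extension_rejected(self, small_genome):
        ref = build_circular_reference(small_genome, 10)
        with pytest.raises(ValueError):
            locate_prefix("A" * 11, ref)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000), st.integers(100, 1_500))
    def test_matches_brute_force_scan(self, seed, length):
        genome = simulate_genome(length, seed)
        ref = build_circular_reference(genome, min(120, length))
        rng = np.random.default_rng(seed + 1)
        p = int(rng.integers(1, length + 1))
        queries = [
            circular_slice(genome.sequence, p, 20),
            reverse_complement(circular_slice(genome.sequence, p, 20)),
            "".join(rng.choice(list("ACGT"), 20)),
        ]
        for q in queries:
            assert locate_prefix(q, ref) == brute_force_locate(q, genome.sequence)


class TestCallTermini:
    def _simulated_calls(self, seed=7, min_ratio=50.0):
        config = SimulationConfig(
            genome_length=20_000, end_type="3prime", overhang_length=9,
            molecule_count=100, read_length=100, intermediate_fraction=0.0, seed=seed,
        )
        genome, reads, truth = run_simulation(config)
        table = count_start_prefixes(reads, 20).bind(genome.length)
        ref = build_circular_reference(genome, 220)
        return call_termini(table, ref, min_ratio), truth

    def test_recovers_planted_termini(self):
        (top, bottom), truth = self._simulated_calls()
        assert top.position == truth.top_terminus_position
        assert bottom.position == truth.bottom_terminus_position
        assert top.frequency == bottom.frequency == truth.molecule_count

    def test_uniform_library_yields_no_terminus(self):
        config = SimulationConfig(
            genome_length=5_000, end_type="3prime", overhang_length=9,
            molecule_count=200, read_length=100, mode="realistic",
            mean_fragment_length=150, intermediate_fraction=1.0, seed=3,
        )
        genome, reads, _ = run_simulation(config)
        table = count_start_prefixes(reads, 20).bind(genome.length)
        top, bottom = call_termini(table, build_circular_reference(genome, 220), 50.0)
        assert top is None and bottom is None

    def test_repeated_top_prefix_is_ambiguity_error(self):
        rng = np.random.default_rng(99)
        seq = list("".join(rng.choice(list("ACGT"), 1000)))
        repeat = "ACCGTTGATCAGGTCCATGA"
        seq[100:120] = repeat
        seq[500:520] = repeat
        genome = GenomeRecord("rep", "".join(seq))
        reads = make_reads([repeat + "ACGT"] * 100)
        table = count_start_prefixes(reads, 20).bind(genome.length)
        ref = build_circular_reference(genome, 220)
        with pytest.raises(AmbiguousTerminusError, match="loci"):
            call_termini(table, ref, 1.0)


class TestGeometry:
    @pytest.mark.parametrize(
        "a,b,L,gap",
        [
            (1, 40_704, 40_713, 9),  # 9-nt 3' cohesive end
            (1, 40_713, 40_713, 0),  # blunt: termini adjacent on the circle
            (1, 12, 48_502, 48_490),  # lambda-like 12-nt 5' overhang: g = L - 12
        ],
    )
    def test_gap_arithmetic(self, a, b, L, gap):
        assert resolve_geometry(a, b, L).gap == gap

    def test_lambda_gap_matches_enumeration(self):
        # count circular positions strictly between b and a going forward
        a, b, L = 1, 12, 48_502
        positions = []
        p = b % L + 1
        while p != a:
            positions.append(p)
            p = p % L + 1
        assert resolve_geometry(a, b, L).gap == len(positions)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 500), st.integers(1, 500), st.integers(0, 499))
    def test_rotation_invariance(self, a, b, r):
        L = 500
        g = resolve_geometry(a, b, L).gap
        a_r = (a - 1 + r) % L + 1
        b_r = (b - 1 + r) % L + 1
        assert resolve_geometry(a_r, b_r, L).gap == g

    def test_position_bounds_enforced(self):
        with pytest.raises(ValueError):
            EndGeometry(top_start=0, bottom_start=1, genome_length=10, gap=0)


class TestExtractOverhang:
    def test_planted_three_prime_tail(self):
        # genome whose planted circular gap spells a known 9-mer
        rng = np.random.default_rng(17)
        body = "".join(rng.choice(list("ACGT"), 991))
        genome = GenomeRecord("toy", body + "TCATCACCG")
        geometry = resolve_geometry(1, 991, genome.length)
        assert geometry.gap == 9
        assert extract_overhang(genome, geometry, "3prime") == "TCATCACCG"

    def test_blunt_is_empty(self):
        geometry = resolve_geometry(1, 100, 100)
        genome = simulate_genome(100, 0)
        assert extract_overhang(genome, geometry, "blunt") == ""

    def test_planted_five_prime_overhang(self):
        config = SimulationConfig(
            genome_length=5_000, end_type="5prime", overhang_length=12,
            molecule_count=10, read_length=100, intermediate_fraction=0.0, seed=8,
        )
        genome, _, truth = run_simulation(config)
        geometry = resolve_geometry(
            truth.top_terminus_position, truth.bottom_terminus_position, genome.length
        )
        assert extract_overhang(genome, geometry, "5prime") == truth.overhang_sequence
        assert len(truth.overhang_sequence) == 12

    def test_unknown_type_rejected(self):
        genome = simulate_genome(100, 0)
        with pytest.raises(ValueError):
            extract_overhang(genome, resolve_geometry(1, 100, 100), "circular")


class TestPositionsReport:
    @pytest.mark.parametrize(
        "L,g,expected_last",
        [(40_713, 9, 40_704), (42_599, 9, 42_590), (100, 0, 100)],
    )
    def test_three_prime_last_base(self, L, g, expected_last):
        geometry = resolve_geometry(1, L - g, L)
        assert geometry.gap == g
        five_prime, three_prime_last = terminus_positions_report(geometry)
        assert five_prime == 1
        assert three_prime_last == expected_last
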