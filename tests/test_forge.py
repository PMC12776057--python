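"""Synthetic haplotype and read generation: determinism, planted structure,
and sampling distributions."""

import dataclasses
import math

import numpy as np
import pytest

from tandemspan import forge
from tandemspan.forge import (
    HaplotypeSpec,
    ReadSimParams,
    WeightedPool,
    build_base_haplotype,
    build_haplotype,
    expand_mmbir,
    recombine_nahr,
    simulate_long_reads,
    simulate_paired_reads,
)


class TestHaplotypeConstruction:
    def test_three_copy_base_structure(self):
        truth = build_base_haplotype(HaplotypeSpec(copy_count=3, seed=1))
        labels = [lab for lab, _, _ in truth.copy_intervals]
        assert labels == ["C1", "C2", "C3A"]
        assert truth.junction_offsets == []

    def test_determinism_byte_identical(self):
        spec = HaplotypeSpec(copy_count=3, seed=1)
        assert build_base_haplotype(spec).sequence == build_base_haplotype(spec).sequence

    def test_ecotype_pair_differs_exactly_at_snp_positions(self):
        spec_m = HaplotypeSpec(ecotype="marine", copy_count=3, seed=7)
        spec_f = dataclasses.replace(spec_m, ecotype="freshwater")
        hm, hf = build_base_haplotype(spec_m), build_base_haplotype(spec_f)
        diff = {
            i for i, (a, b) in enumerate(zip(hm.sequence, hf.sequence)) if a != b
        }
        assert diff == set(hm.snp_table)
        assert len(diff) > 0

    @pytest.mark.parametrize("copies", [4, 5, 6])
    def test_ecotype_invariant_survives_expansion(self, copies):
        crossover = 700 if copies >= 5 else None
        spec_m = HaplotypeSpec(
            ecotype="marine", copy_count=copies, crossover_pos=crossover, seed=3
        )
        spec_f = dataclasses.replace(spec_m, ecotype="freshwater")
        hm, hf = build_haplotype(spec_m), build_haplotype(spec_f)
        diff = {
            i for i, (a, b) in enumerate(zip(hm.sequence, hf.sequence)) if a != b
        }
        assert diff == set(hm.snp_table)

    def test_copy_count_copy_labels_and_junctions(self):
        h6 = build_haplotype(HaplotypeSpec(copy_count=6, crossover_pos=500, seed=2))
        labels = [lab for lab, _, _ in h6.unit_intervals]
        assert labels == ["C3A", "C3B", "C3C", "C3L"]
        assert len(h6.junction_offsets) == h6.copy_count - 3

    def test_invalid_specs_name_the_field(self):
        with pytest.raises(ValueError, match="copy_count"):
            HaplotypeSpec(copy_count=7).validate()
        with pytest.raises(ValueError, match="crossover_pos"):
            HaplotypeSpec(copy_count=3, crossover_pos=10).validate()
        with pytest.raises(ValueError, match="microhomology_len_bp"):
            HaplotypeSpec(microhomology_len_bp=2000).validate()
        with pytest.raises(ValueError, match="gene_length_bp"):
            HaplotypeSpec(gene_length_bp=0).validate()


class TestMmbirExpansion:
    def test_length_increases_by_one_unit(self, marine3):
        h4 = expand_mmbir(marine3)
        assert len(h4.sequence) == len(marine3.sequence) + marine3.geometry.unit
        assert h4.copy_count == 4

    def test_intermediate_mosaic_matches_donor_units(self, fresh5):
        a = fresh5.unit_seq("C3A")
        l = fresh5.unit_seq("C3L")
        b = fresh5.unit_seq("C3B")
        x = fresh5.planted_crossover_pos
        for i in range(len(a)):
            if a[i] != l[i]:
                assert b[i] == (l[i] if i < x else a[i])

    def test_requested_microhomology_must_match_plant(self, marine3):
        with pytest.raises(ValueError, match="microhomology"):
            expand_mmbir(marine3, microhomology_len_bp=9)


class TestNahrRecombination:
    def test_reciprocal_products_4plus4(self, fresh4):
        dup, dele = recombine_nahr(fresh4, fresh4, ("C3A", "C3L"), 700)
        assert (dup.copy_count, dele.copy_count) == (5, 3)

    def test_offset_pairing_of_five_copy_haplotypes(self):
        h5 = build_haplotype(
            HaplotypeSpec(ecotype="freshwater", copy_count=5, crossover_pos=None, seed=9)
        )
        dup, dele = recombine_nahr(h5, h5, ("C3A", "C3B"), 400)
        assert (dup.copy_count, dele.copy_count) == (6, 4)

    @pytest.mark.parametrize(
        "pairing", [("C3A", "C3L"), ("C3L", "C3A"), ("C3A", "C3A")]
    )
    def test_copy_conservation(self, fresh4, pairing):
        dup, dele = recombine_nahr(fresh4, fresh4, pairing, 250)
        assert dup.copy_count + dele.copy_count == 2 * fresh4.copy_count

    def test_duplication_intermediate_is_l_then_a(self, fresh4):
        dup, _ = recombine_nahr(fresh4, fresh4, ("C3A", "C3L"), 800)
        a, b, l = (dup.unit_seq(k) for k in ("C3A", "C3B", "C3L"))
        for i in range(len(a)):
            if a[i] != l[i]:
                assert b[i] == (l[i] if i < 800 else a[i])

    def test_planted_interval_contains_crossover(self, fresh4):
        dup, _ = recombine_nahr(fresh4, fresh4, ("C3A", "C3L"), 800)
        lo, hi = dup.planted_crossover_interval
        assert lo <= 800 <= hi

    def test_crossover_outside_unit_rejected(self, fresh4):
        with pytest.raises(ValueError, match="crossover_pos"):
            recombine_nahr(fresh4, fresh4, ("C3A", "C3L"), 10**6)


class TestPairedReadSimulation:
    def test_count_and_length_contract(self, marine3):
        pool = WeightedPool.of(("h", marine3.sequence, 1.0))
        pairs = simulate_paired_reads(
            pool, ReadSimParams(n_pairs=1000, depth_x=None, read_len_bp=76, seed=4)
        )
        assert len(pairs) == 1000
        assert all(len(p.r1) == 76 and len(p.r2) == 76 for p in pairs)

    def test_realized_depth_near_target(self, marine3):
        pool = WeightedPool.of(("h", marine3.sequence, 1.0))
        params = ReadSimParams(depth_x=8.0, seed=5)
        pairs = simulate_paired_reads(pool, params)
        realized = 2 * 76 * len(pairs) / len(marine3.sequence)
        # n_pairs is rounded deterministically, so realized depth is within
        # one pair of the target
        assert abs(realized - 8.0) < 2 * 76 / len(marine3.sequence) + 1e-9

    def test_source_weights_respected(self):
        seq = "ACGT" * 2500
        pool = WeightedPool.of(("x", seq, 3.0), ("y", seq, 1.0))
        pairs = simulate_paired_reads(
            pool, ReadSimParams(n_pairs=8000, depth_x=None, seed=6)
        )
        n_x = sum(p.source == "x" for p in pairs)
        p_hat = n_x / len(pairs)
        se = math.sqrt(0.75 * 0.25 / len(pairs))
        assert abs(p_hat - 0.75) < 3 * se

    def test_per_base_errors_applied_at_rate(self, marine3):
        pool = WeightedPool.of(("h", marine3.sequence, 1.0))
        params = ReadSimParams(n_pairs=2000, depth_x=None, per_base_error=0.02, seed=8)
        pairs = simulate_paired_reads(pool, params)
        mismatches = bases = 0
        for p in pairs:
            true = marine3.sequence[p.frag_start : p.frag_start + 76]
            mismatches += sum(a != b for a, b in zip(p.r1, true))
            bases += 76
        rate = mismatches / bases
        se = math.sqrt(0.02 * 0.98 / bases)
        assert abs(rate - 0.02) < 4 * se

    def test_all_sequences_too_short_rejected(self):
        pool = WeightedPool.of(("s", "ACGT" * 5, 1.0))
        with pytest.raises(ValueError, match="shorter"):
            simulate_paired_reads(pool, ReadSimParams(n_pairs=10, depth_x=None))

    def test_reproducible_from_seed(self, marine3):
        pool = WeightedPool.of(("h", marine3.sequence, 1.0))
        params = ReadSimParams(n_pairs=50, depth_x=None, per_base_error=0.01, seed=12)
        assert simulate_paired_reads(pool, params) == simulate_paired_reads(pool, params)


class TestLongReadSimulation:
    def test_zero_reads(self):
        pool = WeightedPool.of(("a", "ACGTACGT", 1.0))
        assert simulate_long_reads(pool, 0) == []

    def test_equal_weights_split(self):
        pool = WeightedPool.of(("a", "ACGT" * 100, 1.0), ("b", "TTGG" * 100, 1.0))
        reads = simulate_long_reads(pool, 10000, seed=13)
        n_a = sum(r.source == "a" for r in reads)
        se = math.sqrt(0.25 / 10000)
        assert abs(n_a / 10000 - 0.5) < 3 * se

    def test_truncation_rate(self):
        pool = WeightedPool.of(("a", "ACGT" * 100, 1.0))
        reads = simulate_long_reads(pool, 4000, seed=14, truncation_rate=0.5)
        frac_short = sum(len(r.seq) < 400 for r in reads) / len(reads)
        se = math.sqrt(0.25 / 4000)
        assert abs(frac_short - 0.5) < 3 * se


class TestWeightedPool:
    def test_validation(self):
        with pytest.raises(ValueError, match="unique"):
            WeightedPool.of(("a", "ACGT", 1.0), ("a", "ACGT", 1.0))
        with pytest.raises(ValueError, match="weight"):
            WeightedPool.of(("a", "ACGT", 0.0))
        with pytest.raises(ValueError):
            WeightedPool(())
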