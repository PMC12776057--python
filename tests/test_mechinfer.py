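"""Microhomology detection and crossover-window inference, checked against
exhaustive oracles and forge-planted ground truth."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tandemspan import forge, mechinfer
from tandemspan.forge import HaplotypeSpec, build_haplotype
from tandemspan.mechinfer import (
    CrossoverWindow,
    DivergentColumn,
    JunctionContext,
    classify_intermediate,
    compare_crossovers,
    crossover_analysis,
    divergent_columns,
    infer_crossover_window,
    junction_microhomology,
    strip_gap_columns,
)


class TestJunctionMicrohomology:
    def _ctx(self, left, right, off_l, off_r, window=20):
        return JunctionContext(
            junction_pos=0,
            left_donor=left,
            left_offset=off_l,
            right_donor=right,
            right_offset=off_r,
            flank_window=window,
        )

    def test_planted_core_detected(self):
        # donors share ACGT immediately left of the junction, divergent flanks
        left = "TTTTTTTTACGTGGGGG"
        right = "CCCCCCCCACGTAAAAA"
        res = junction_microhomology(self._ctx(left, right, 12, 12))
        assert res.perfect_len == 4

    def test_fully_divergent_donors(self):
        res = junction_microhomology(self._ctx("AAAAAA", "CCCCCC", 3, 3))
        assert res.perfect_len == 0

    def test_imperfect_window_with_one_mismatch(self):
        # 8-base window containing a 4-base perfect core and one mismatch
        left = "TTTT" + "ACG" + "T" + "GCTA" + "GGGG"
        right = "CCCC" + "ACG" + "A" + "GCTA" + "AAAA"
        res = junction_microhomology(self._ctx(left, right, 12, 12))
        assert res.perfect_len == 4
        assert res.imperfect_len == 8

    @pytest.mark.parametrize("k", [0, 2, 4, 8])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_on_forge_plants(self, k, seed):
        spec = HaplotypeSpec(copy_count=4, microhomology_len_bp=k, seed=seed)
        hap = build_haplotype(spec)
        res = junction_microhomology(hap.junction_context(0))
        assert res.perfect_len == k

    @pytest.mark.parametrize("seed", [3, 4])
    def test_imperfect_roundtrip(self, seed):
        spec = HaplotypeSpec(
            copy_count=4, microhomology_len_bp=4,
            imperfect_microhomology_bp=8, seed=seed,
        )
        hap = build_haplotype(spec)
        res = junction_microhomology(hap.junction_context(0))
        assert (res.perfect_len, res.imperfect_len) == (4, 8)

    def test_matches_window_scan_oracle_on_random_donors(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            left = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
            right = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
            ctx = self._ctx(left, right, 20, 20, window=15)
            res = junction_microhomology(ctx, mismatch_budget=1)
            # independent oracle: enumerate all junction-region windows
            match = [left[20 + d] == right[20 + d] for d in range(-15, 15)]
            a = 0
            while a < 15 and match[15 - a - 1]:
                a += 1
            b = 0
            while b < 15 and match[15 + b]:
                b += 1
            best = a + b
            for i in range(0, 15 - a + 1):
                for j in range(15 + b, 31):
                    win = match[i:j]
                    if (j - i) > best and win.count(False) <= 1:
                        best = j - i
            assert res.perfect_len == a + b
            assert res.imperfect_len == best

    def test_empty_donor_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            junction_microhomology(self._ctx("", "ACGT", 0, 2))


class TestDivergentColumns:
    def test_single_divergent_column(self):
        cols = divergent_columns({"A": "AAAA", "L": "AATA", "B": "AATA"})
        assert cols == [DivergentColumn(position=2, a_base="A", l_base="T")]

    def test_gap_columns_removed_before_positions_assigned(self):
        aln = strip_gap_columns({"A": "A-CA", "L": "A-TA", "B": "A-TA"})
        cols = divergent_columns(aln)
        assert cols == [DivergentColumn(position=1, a_base="C", l_base="T")]

    def test_intermediate_only_variant_excluded(self):
        cols = divergent_columns({"A": "AAAA", "L": "AAAA", "B": "ATAA"})
        assert cols == []

    def test_missing_required_row(self):
        with pytest.raises(ValueError, match="'L'"):
            divergent_columns({"A": "AAAA", "B": "AATA"})


class TestClassification:
    COLS = [DivergentColumn(0, "A", "T"), DivergentColumn(1, "C", "G")]

    def test_labels(self):
        labels = classify_intermediate(self.COLS, "AG")
        assert labels == [(0, "A"), (1, "L")]

    def test_third_base_is_other(self):
        labels = classify_intermediate(self.COLS, "GT")
        assert labels == [(0, "other"), (1, "other")]


def oracle_changepoint(labels):
    """Brute-force minimum mismatches of the L-then-A model and its optima."""
    n = len(labels)
    costs = [
        sum(lab == "A" for lab in labels[:c]) + sum(lab == "L" for lab in labels[c:])
        for c in range(n + 1)
    ]
    best = min(costs)
    return best, [c for c in range(n + 1) if costs[c] == best]


class TestCrossoverWindow:
    def test_clean_transition(self):
        w = infer_crossover_window([(1, "L"), (2, "L"), (3, "L"), (4, "A"), (5, "A")])
        assert (w.lo, w.hi) == (3, 4)
        assert w.mismatches == 0

    def test_conversion_like_residual(self):
        w = infer_crossover_window(
            [(1, "L"), (2, "L"), (3, "A"), (4, "A"), (5, "L"), (6, "A")]
        )
        assert (w.lo, w.hi) == (2, 3)
        assert w.mismatches == 1
        assert w.conversion_positions == (5,)

    def test_reversed_orientation_flagged(self):
        w = infer_crossover_window([(1, "A"), (2, "A"), (3, "L"), (4, "L")])
        assert w.non_canonical

    def test_degenerate_all_one_state(self):
        w = infer_crossover_window([(1, "L"), (2, "L"), (3, "L")])
        assert w.degenerate

    def test_other_labels_ignored(self):
        w = infer_crossover_window(
            [(1, "L"), (2, "other"), (3, "L"), (4, "A"), (5, "A")]
        )
        assert (w.lo, w.hi) == (3, 4)

    def test_too_few_informative_labels(self):
        with pytest.raises(ValueError, match="2 informative"):
            infer_crossover_window([(1, "L"), (2, "other")])

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.sampled_from("LA"), min_size=2, max_size=12))
    def test_matches_exhaustive_oracle(self, labels):
        labeled = [(i * 3 + 1, lab) for i, lab in enumerate(labels)]
        w = infer_crossover_window(labeled)
        best, optima = oracle_changepoint(labels)
        assert w.mismatches == best
        assert w.changepoints == tuple(optima)

    def test_all_label_strings_up_to_length_8_exhaustive(self):
        for n in range(2, 9):
            for labels in itertools.product("LA", repeat=n):
                w = infer_crossover_window(list(enumerate(labels)))
                best, optima = oracle_changepoint(list(labels))
                assert w.mismatches == best
                assert w.changepoints == tuple(optima)

    def test_window_union_over_tied_optima(self):
        # L A at positions 1, 10: optimal changepoints are c=1 only
        w = infer_crossover_window([(1, "L"), (10, "A")])
        assert (w.lo, w.hi) == (1, 10)

    def test_containment_on_forge_nahr_products(self):
        """The inferred window contains the planted crossover in >=95% of
        replicates with >=10 informative columns on either side."""
        n_ok = n = 0
        for seed in range(100):
            spec = HaplotypeSpec(
                copy_count=5,
                dup_region_length_bp=4000,
                crossover_pos=2000,
                unit_divergence_rate=0.012,
                seed=700 + seed,
            )
            hap = build_haplotype(spec)
            aln = {
                "A": hap.unit_seq("C3A"),
                "L": hap.unit_seq("C3L"),
                "B": hap.unit_seq("C3B"),
            }
            win = crossover_analysis(aln)["B"]
            n += 1
            n_ok += win.lo <= hap.planted_crossover_pos <= win.hi
        assert n_ok / n >= 0.95


class TestCompareCrossovers:
    def test_identical_windows_one_group(self):
        _, n = compare_crossovers({"x": (10, 20), "y": (10, 20)})
        assert n == 1

    def test_disjoint_windows_two_groups(self):
        _, n = compare_crossovers({"x": (10, 20), "y": (30, 40)})
        assert n == 2

    def test_five_shared_one_disjoint(self):
        windows = {
            "JADE": (2451, 2596),
            "ECHO": (2451, 2932),
            "CMCB": (2451, 2932),
            "DNSE": (2451, 2932),
            "KFSY": (2451, 2932),
            "BLAU": (4246, 4730),
        }
        groups, n = compare_crossovers(windows)
        assert n == 2
        assert {frozenset(g) for g in groups} == {
            frozenset({"JADE", "ECHO", "CMCB", "DNSE", "KFSY"}),
            frozenset({"BLAU"}),
        }

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_crossovers({"x": (5, 5)})
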