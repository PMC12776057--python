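"""K-mer design, screening, exact pair counting, and ASE estimation."""

import math

import numpy as np
import pytest

from tandemspan._seq import revcomp
from tandemspan import forge, kmerquant
from tandemspan.kmerquant import (
    ParalogAlignment,
    ase_proportion,
    ase_test,
    count_pairs,
    design_kmers,
    mce_rpm,
    screen_kmers,
)


def _mut(s, pos, base):
    return s[:pos] + base + s[pos + 1 :]


def _other(base, off=1):
    return "ACGT"[("ACGT".index(base) + off) % 4]


def toy_alignment(length=300, copy_cols=(150,), allele_cols=(), seed=0):
    """Alignment of copies X/Y with a shared base; planted copy-diagnostic
    columns (Y differs) and allele-diagnostic columns (Y's allele b differs)."""
    rng = np.random.default_rng(seed)
    base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    y = base
    for c in copy_cols:
        y = _mut(y, c, _other(base[c]))
    yb = y
    for c in allele_cols:
        yb = _mut(yb, c, _other(y[c]))
    return ParalogAlignment(
        rows={("X", "a"): base, ("X", "b"): base, ("Y", "a"): y, ("Y", "b"): yb}
    )


class TestDesign:
    def test_mce_windows_cover_the_copy_column(self):
        aln = toy_alignment(copy_cols=(150,))
        sets = design_kmers(aln, "MCE", non_overlapping=False)
        # brute force: exactly the gap-free 27-column windows overlapping 150
        expected = {
            s for s in range(aln.length - 26) if s <= 150 <= s + 26
        }
        assert {ks.source_columns[0] for ks in sets} == expected
        for ks in sets:
            assert len(set(ks.members.values())) == 2

    def test_ase_requires_both_column_kinds_within_window(self):
        aln = toy_alignment(copy_cols=(150,), allele_cols=(160,))
        sets = design_kmers(aln, "ASE", target="Y", non_overlapping=False)
        assert sets, "copy and allele variants 10 bp apart must yield candidates"
        for ks in sets:
            lo, hi = ks.source_columns
            assert lo <= 150 < hi and lo <= 160 < hi

    def test_no_ase_candidate_when_columns_too_far(self):
        aln = toy_alignment(length=400, copy_cols=(150,), allele_cols=(190,))
        assert design_kmers(aln, "ASE", target="Y") == []

    def test_no_qualifying_columns_yields_empty(self):
        aln = toy_alignment(copy_cols=(), allele_cols=())
        assert design_kmers(aln, "MCE") == []
        assert design_kmers(aln, "ASE", target="Y") == []

    def test_non_overlapping_selection(self):
        aln = toy_alignment(copy_cols=(150,))
        sets = design_kmers(aln, "MCE", non_overlapping=True)
        spans = sorted(ks.source_columns for ks in sets)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            assert a_hi <= b_lo


class TestScreen:
    def test_perfect_off_target_match_removes_set(self):
        aln = toy_alignment(copy_cols=(150,), allele_cols=(160,))
        sets = design_kmers(aln, "ASE", target="Y")
        member = next(iter(sets[0].members.values()))
        refs = {"target": aln.rows[("Y", "a")], "decoy": "T" * 40 + member + "A" * 40}
        target_regions = {"target": [(0, aln.length)]}
        kept = screen_kmers(sets, refs, target_regions, min_end_distance=0)
        assert sets[0] not in kept

    def test_one_mismatch_budget_boundary(self):
        rng = np.random.default_rng(11)
        kmer = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 27)])
        ks = kmerquant.KmerSet(
            id="s", mode="MCE", target="", members={"X": kmer},
            source_columns=(0, 27),
        )

        def decoy(n_hits):
            # NNNN separators: windows crossing a boundary are misaligned
            # against the k-mer and cannot be spurious 1-mismatch hits
            variant = _mut(kmer, 13, _other(kmer[13]))
            return "NNNN".join([variant] * n_hits)

        ok = screen_kmers([ks], {"d": decoy(5)}, min_end_distance=0)
        assert ks in ok
        gone = screen_kmers([ks], {"d": decoy(6)}, min_end_distance=0)
        assert ks not in gone

    def test_transcript_end_distance(self):
        aln = toy_alignment(length=160, copy_cols=(130,))
        sets = design_kmers(aln, "MCE", non_overlapping=False)
        # windows ending within 100 bp of the transcript end must be dropped
        kept = screen_kmers(sets, {}, min_end_distance=100)
        assert kept == []
        kept_relaxed = screen_kmers(sets, {}, min_end_distance=0)
        assert kept_relaxed


def brute_force_counts(pairs, sets, rc=True):
    out = {ks.id: {k: 0 for k in ks.members} for ks in sets}
    for r1, r2 in pairs:
        for ks in sets:
            for key, km in ks.members.items():
                pats = [km, revcomp(km)] if rc else [km]
                hit = any(
                    read[i : i + len(km)] in pats
                    for read in (r1, r2)
                    for i in range(len(read) - len(km) + 1)
                )
                out[ks.id][key] += hit
    return out


@pytest.fixture(scope="module")
def fixture():
    aln = toy_alignment(length=600, copy_cols=(300,), allele_cols=(310,), seed=3)
    sets = design_kmers(aln, "ASE", target="Y") + design_kmers(aln, "MCE")
    pool = forge.WeightedPool.of(
        ("Ya", aln.rows[("Y", "a")], 1.0), ("Yb", aln.rows[("Y", "b")], 1.0)
    )
    pairs = forge.simulate_paired_reads(
        pool,
        forge.ReadSimParams(n_pairs=1000, depth_x=None, per_base_error=0.005, seed=4),
    )
    return sets, [(p.r1, p.r2) for p in pairs]


class TestCounting:
    def test_pair_counted_once_even_if_both_mates_match(self):
        kmer = "A" * 27
        ks = kmerquant.KmerSet(
            id="s", mode="MCE", target="", members={"X": kmer},
            source_columns=(0, 27),
        )
        res = count_pairs([("A" * 40, "A" * 40)], [ks])
        assert res.counts["s"]["X"] == 1

    def test_single_mismatch_is_no_match(self):
        kmer = "A" * 27
        ks = kmerquant.KmerSet(
            id="s", mode="MCE", target="", members={"X": kmer},
            source_columns=(0, 27),
        )
        read = "A" * 13 + "C" + "A" * 13
        res = count_pairs([(read, "G" * 27)], [ks])
        assert res.counts["s"]["X"] == 0

    def test_equals_brute_force_oracle(self, fixture):
        sets, pairs = fixture
        fast = count_pairs(pairs, sets)
        assert fast.counts == brute_force_counts(pairs, sets)
        assert fast.total_pairs == len(pairs)

    def test_stranded_mode_equals_oracle_without_rc(self, fixture):
        sets, pairs = fixture
        fast = count_pairs(pairs[:200], sets, search_reverse_complement=False)
        assert fast.counts == brute_force_counts(pairs[:200], sets, rc=False)

    def test_design_soundness_single_allele_reads(self):
        """Reads from one allele never count toward the other allele."""
        aln = toy_alignment(length=600, copy_cols=(300,), allele_cols=(310,), seed=5)
        sets = design_kmers(aln, "ASE", target="Y")
        pool = forge.WeightedPool.of(("Ya", aln.rows[("Y", "a")], 1.0))
        pairs = forge.simulate_paired_reads(
            pool, forge.ReadSimParams(n_pairs=500, depth_x=None, seed=6)
        )
        counts = count_pairs([(p.r1, p.r2) for p in pairs], sets)
        for ks in sets:
            assert counts.counts[ks.id]["b"] == 0


class TestRpm:
    def _counts(self, n, total):
        ks = kmerquant.KmerSet(
            id="m1", mode="MCE", target="", members={"X": "A" * 27},
            source_columns=(0, 27),
        )
        return ks, kmerquant.KmerCounts(counts={"m1": {"X": n}}, total_pairs=total)

    def test_formula(self):
        ks, counts = self._counts(50, 1_000_000)
        assert mce_rpm(counts, [ks]) == {"X": 50.0}

    def test_zero_detections(self):
        ks, counts = self._counts(0, 10)
        assert mce_rpm(counts, [ks]) == {"X": 0.0}

    def test_linearity_in_detections(self):
        ks, c1 = self._counts(30, 1_000_000)
        _, c2 = self._counts(60, 1_000_000)
        assert mce_rpm(c2, [ks])["X"] == 2 * mce_rpm(c1, [ks])["X"]

    def test_mean_across_sets_for_one_copy(self):
        k1 = kmerquant.KmerSet(id="a", mode="MCE", target="", members={"X": "A" * 27}, source_columns=(0, 27))
        k2 = kmerquant.KmerSet(id="b", mode="MCE", target="", members={"X": "C" * 27}, source_columns=(30, 57))
        counts = kmerquant.KmerCounts(
            counts={"a": {"X": 10}, "b": {"X": 20}}, total_pairs=1_000_000
        )
        assert mce_rpm(counts, [k1, k2])["X"] == 15.0

    def test_zero_total_pairs_rejected(self):
        ks, _ = self._counts(0, 10)
        counts = kmerquant.KmerCounts(counts={"m1": {"X": 0}}, total_pairs=0)
        with pytest.raises(ValueError, match="total_pairs"):
            mce_rpm(counts, [ks])


def _ase_sets_and_counts(per_set_counts, total=10_000):
    sets, counts = [], {}
    for i, (c1, c2) in enumerate(per_set_counts):
        sid = f"ase{i}"
        sets.append(
            kmerquant.KmerSet(
                id=sid, mode="ASE", target="C3",
                members={"a1": "A" * 26 + "ACGT"[i], "a2": "C" * 26 + "ACGT"[i]},
                source_columns=(0, 27),
            )
        )
        counts[sid] = {"a1": c1, "a2": c2}
    return sets, kmerquant.KmerCounts(counts=counts, total_pairs=total)


class TestAse:
    def test_basic_proportion(self):
        sets, counts = _ase_sets_and_counts([(75, 25)])
        res = ase_proportion(counts, sets, "C3", allele1="a1")
        assert res.qc_pass and res.proportion_allele1 == pytest.approx(0.75)

    def test_min_total_reads_qc(self):
        sets, counts = _ase_sets_and_counts([(66, 33)])
        res = ase_proportion(counts, sets, "C3")
        assert not res.qc_pass and res.qc_reason == "min total reads"

    def test_missing_allele_qc(self):
        sets, counts = _ase_sets_and_counts([(200, 0)])
        res = ase_proportion(counts, sets, "C3")
        assert not res.qc_pass and res.qc_reason == "missing allele"

    def test_undetected_set_qc(self):
        sets, counts = _ase_sets_and_counts([(100, 50), (0, 0)])
        res = ase_proportion(counts, sets, "C3")
        assert not res.qc_pass and res.qc_reason == "k-mer set undetected"

    def test_average_across_sets(self):
        sets, counts = _ase_sets_and_counts([(80, 20), (60, 40)])
        res = ase_proportion(counts, sets, "C3", allele1="a1")
        assert res.proportion_allele1 == pytest.approx(0.7)
        assert res.n_sets_used == 2

    def test_copy_proportional_fixture_recovers_75_percent(self, transcript_family):
        """A diploid with a 3:1 copy ratio and equal per-copy expression
        yields an allele proportion near the 75% dosage prediction."""
        aln = ParalogAlignment(rows=transcript_family)
        sets = kmerquant.design_kmers(aln, "ASE", target="C3")
        pool = forge.WeightedPool.of(
            ("f", transcript_family[("C3", "freshwater")], 3.0),
            ("m", transcript_family[("C3", "marine")], 1.0),
        )
        pairs = forge.simulate_paired_reads(
            pool, forge.ReadSimParams(n_pairs=6000, depth_x=None, seed=8)
        )
        counts = count_pairs([(p.r1, p.r2) for p in pairs], sets)
        res = ase_proportion(counts, sets, "C3", allele1="freshwater")
        assert res.qc_pass
        n_inf = sum(sum(v.values()) for v in counts.counts.values())
        se = math.sqrt(0.75 * 0.25 / n_inf)
        assert abs(res.proportion_allele1 - 0.75) < 4 * se + 0.01


class TestAseTest:
    def test_six_positive_replicates_exact(self):
        p = ase_test([0.6, 0.62, 0.7, 0.55, 0.58, 0.61])
        assert p == pytest.approx(2 / 64)

    def test_symmetric_values_uninformative(self):
        assert ase_test([0.4, 0.6, 0.45, 0.55]) == pytest.approx(1.0)

    def test_single_replicate_flagged(self):
        with pytest.warns(UserWarning, match="single"):
            assert ase_test([0.8]) == 1.0

    def test_all_at_mu_warns(self):
        with pytest.warns(UserWarning, match="equal mu"):
            assert ase_test([0.5, 0.5, 0.5]) == 1.0

    def test_two_group_comparison(self):
        p = kmerquant.ase_group_test([0.6, 0.61, 0.62], [0.5, 0.51, 0.52])
        assert p == pytest.approx(0.1)
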