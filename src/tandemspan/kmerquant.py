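"""Discriminating k-mer quantification of near-identical paralog expression.

Reference mapping of short RNA reads is unreliable for gene copies that are
>98% identical, so expression is quantified by exact matching of 27-mers
designed on an alignment of all copies for both alleles:

* **MCE (copy-expression) k-mers** target the homologous window in every
  copy: the window is allele-invariant but contains at least one column that
  distinguishes the copies, yielding one 27-mer per copy. Matched read-pair
  counts normalized per million pairs compare relative copy expression while
  cancelling positional coverage effects.

* **ASE (allele-specific) k-mers** contain at least one copy-diagnostic and
  at least one allele-diagnostic column, yielding one 27-mer per allele of a
  single target copy. The allele-1 proportion of matched pairs, averaged
  across k-mer sets, estimates allele-specific expression.

Candidate k-mers are screened against reference genomes (no perfect
off-target match; at most 5 one-mismatch off-target matches) and must sit at
least 100 bp from transcript ends where coverage decays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import revcomp

__all__ = [
    "ParalogAlignment",
    "KmerSet",
    "KmerCounts",
    "AseResult",
    "design_kmers",
    "screen_kmers",
    "count_pairs",
    "mce_rpm",
    "expected_allele_proportion",
    "ase_proportion",
    "ase_test",
    "ase_group_test",
]

K_DEFAULT = 27
GAPS = set("-.")


# ---------------------------------------------------------------------------
# alignment and column classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParalogAlignment:
    """Aligned exonic sequences of every copy for both alleles.

    ``rows`` maps (copy_label, allele_label) -> aligned sequence. The two
    allele labels play the role of the marine and freshwater haplotypes.
    """

    rows: dict[tuple[str, str], str]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment must have rows")
        if len({len(s) for s in self.rows.values()}) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def copies(self) -> list[str]:
        return sorted({c for c, _ in self.rows})

    @property
    def alleles(self) -> list[str]:
        return sorted({a for _, a in self.rows})

    def classify_columns(self) -> list[str]:
        """Per-column class: copy / allele / invariant / other.

        * ``copy``: no within-copy allele difference, and some pair of copies
          carries different bases (copy-discriminating, allele-invariant);
        * ``allele``: some copy's two alleles differ, copies otherwise agree;
        * ``invariant``: one base across all rows;
        * ``other``: gap columns, or columns mixing both kinds of signal.
        """
        out = []
        copies, alleles = self.copies, self.alleles
        for c in range(self.length):
            col = {key: seq[c] for key, seq in self.rows.items()}
            if any(b in GAPS for b in col.values()):
                out.append("other")
                continue
            per_copy = {
                cp: {col[(cp, al)] for al in alleles if (cp, al) in col}
                for cp in copies
            }
            allele_diff = any(len(s) > 1 for s in per_copy.values())
            union_per_copy = [s for s in per_copy.values()]
            copy_diff = any(
                a.isdisjoint(b)
                for i, a in enumerate(union_per_copy)
                for b in union_per_copy[i + 1 :]
            )
            if not allele_diff and not copy_diff:
                out.append("invariant")
            elif copy_diff and not allele_diff:
                out.append("copy")
            elif allele_diff and not copy_diff:
                out.append("allele")
            else:
                out.append("other")
        return out

    def ungapped_offset(self, key: tuple[str, str], column: int) -> int:
        """Offset of an alignment column within the row's ungapped sequence."""
        seq = self.rows[key]
        return sum(1 for ch in seq[:column] if ch not in GAPS)

    def ungapped_length(self, key: tuple[str, str]) -> int:
        return sum(1 for ch in self.rows[key] if ch not in GAPS)


@dataclass(frozen=True)
class KmerSet:
    """One discriminating k-mer family from a single alignment window.

    MCE mode: one member per copy (keyed by copy label). ASE mode: one member
    per allele of the target copy (keyed by allele label).
    """

    id: str
    mode: str                       # "MCE" or "ASE"
    target: str                     # target copy label (ASE) or "" (MCE)
    members: dict[str, str]         # key -> 27-mer string
    source_columns: tuple[int, int]  # window [start, end) in alignment columns
    k: int = K_DEFAULT
    end_distances: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("MCE", "ASE"):
            raise ValueError("mode must be MCE or ASE")
        if any(len(m) != self.k for m in self.members.values()):
            raise ValueError(f"all members must be {self.k}-mers")
        if len(set(self.members.values())) != len(self.members):
            raise ValueError("member k-mers must be mutually distinct")


def _window_kmers(
    alignment: ParalogAlignment, start: int, k: int
) -> dict[tuple[str, str], str]:
    return {key: seq[start : start + k] for key, seq in alignment.rows.items()}


def design_kmers(
    alignment: ParalogAlignment,
    mode: str,
    k: int = K_DEFAULT,
    target: str | None = None,
    non_overlapping: bool = True,
) -> list[KmerSet]:
    """Enumerate qualifying k-column windows and emit candidate k-mer sets.

    A window must be gap-free in every row. MCE windows contain >=1
    copy-discriminating column and no allele signal; every pair of copies
    must be distinguished within the window. ASE windows (for each target
    copy, or just ``target``) contain >=1 allele-diagnostic column of the
    target and >=1 column separating the target from every other copy.

    With ``non_overlapping`` (default), overlapping candidates for the same
    target are reduced greedily left to right.
    """
    classes = alignment.classify_columns()
    alleles = alignment.alleles
    copies = alignment.copies
    out: list[KmerSet] = []

    def end_distances(key, start):
        off = alignment.ungapped_offset(key, start)
        total = alignment.ungapped_length(key)
        return (off, total - (off + k))

    if mode == "MCE":
        for start in range(alignment.length - k + 1):
            win = classes[start : start + k]
            if any(cls in ("allele", "other") for cls in win):
                continue
            if "copy" not in win:
                continue
            kmers = _window_kmers(alignment, start, k)
            members = {cp: kmers[(cp, alleles[0])] for cp in copies}
            if len(set(members.values())) != len(members):
                continue  # some copy pair not distinguished in this window
            out.append(
                KmerSet(
                    id=f"MCE_{start}",
                    mode="MCE",
                    target="",
                    members=members,
                    source_columns=(start, start + k),
                    k=k,
                    end_distances={
                        cp: end_distances((cp, alleles[0]), start) for cp in copies
                    },
                )
            )
    elif mode == "ASE":
        if len(alleles) != 2:
            raise ValueError("ASE design requires exactly two alleles")
        targets = [target] if target is not None else copies
        for tgt in targets:
            for start in range(alignment.length - k + 1):
                kmers = _window_kmers(alignment, start, k)
                if any(
                    ch in GAPS for s in kmers.values() for ch in s
                ):
                    continue
                m1, m2 = kmers[(tgt, alleles[0])], kmers[(tgt, alleles[1])]
                if m1 == m2:
                    continue  # no allele-diagnostic variant for the target
                others = [
                    kmers[(cp, al)]
                    for cp in copies
                    if cp != tgt
                    for al in alleles
                    if (cp, al) in kmers
                ]
                if any(m1 == o for o in others) or any(m2 == o for o in others):
                    continue  # target not separated from every other copy
                out.append(
                    KmerSet(
                        id=f"ASE_{tgt}_{start}",
                        mode="ASE",
                        target=tgt,
                        members={alleles[0]: m1, alleles[1]: m2},
                        source_columns=(start, start + k),
                        k=k,
                        end_distances={
                            al: end_distances((tgt, al), start) for al in alleles
                        },
                    )
                )
    else:
        raise ValueError("mode must be MCE or ASE")

    if non_overlapping:
        selected: list[KmerSet] = []
        last_end: dict[str, int] = {}
        for ks in sorted(out, key=lambda s: (s.target, s.source_columns)):
            if ks.source_columns[0] >= last_end.get(ks.target, -1):
                selected.append(ks)
                last_end[ks.target] = ks.source_columns[1]
        out = selected
    return out


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _match_counts(ref: np.ndarray, kmer: str) -> tuple[list[int], list[int]]:
    """Positions of exact and exactly-one-mismatch occurrences of kmer in a
    (forward-strand) encoded reference."""
    k = len(kmer)
    if len(ref) < k:
        return [], []
    q = _encode(kmer)
    n = len(ref) - k + 1
    mism = np.zeros(n, dtype=np.int32)
    for j in range(k):
        mism += ref[j : j + n] != q[j]
    exact = np.nonzero(mism == 0)[0].tolist()
    one = np.nonzero(mism == 1)[0].tolist()
    return exact, one


def screen_kmers(
    candidates: list[KmerSet],
    references: dict[str, str],
    target_regions: dict[str, list[tuple[int, int]]] | None = None,
    max_one_mismatch: int = 5,
    min_end_distance: int = 100,
) -> list[KmerSet]:
    """Retain candidate sets passing all quality filters.

    A set survives only if every member has zero perfect off-target matches
    and at most ``max_one_mismatch`` one-mismatch off-target matches in the
    reference genomes (both strands), and lies at least ``min_end_distance``
    bp from both ends of its transcript. Matches inside ``target_regions``
    — the homologous positions across copies and alleles — are on-target
    and not counted.
    """
    target_regions = target_regions or {}
    enc = {name: _encode(seq) for name, seq in references.items()}

    def off_target(name: str, pos: int, k: int) -> bool:
        for lo, hi in target_regions.get(name, []):
            if pos < hi and pos + k > lo:
                return False
        return True

    kept = []
    for ks in candidates:
        ok = True
        for key, kmer in ks.members.items():
            d5, d3 = ks.end_distances.get(key, (min_end_distance, min_end_distance))
            if d5 < min_end_distance or d3 < min_end_distance:
                ok = False
                break
            perfect_off = 0
            one_off = 0
            for name, ref in enc.items():
                for query in (kmer, revcomp(kmer)):
                    exact, one = _match_counts(ref, query)
                    perfect_off += sum(off_target(name, p, ks.k) for p in exact)
                    one_off += sum(off_target(name, p, ks.k) for p in one)
            if perfect_off > 0 or one_off > max_one_mismatch:
                ok = False
                break
        if ok:
            kept.append(ks)
    return kept


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerCounts:
    """Matched-pair counts per k-mer set member, plus the library size."""

    counts: dict[str, dict[str, int]]  # set id -> member key -> pairs matched
    total_pairs: int

    def __post_init__(self):
        if any(
            c < 0 or c > self.total_pairs
            for per_set in self.counts.values()
            for c in per_set.values()
        ):
            raise ValueError("counts must be within [0, total_pairs]")


def count_pairs(
    pairs,
    kmer_sets: list[KmerSet],
    search_reverse_complement: bool = True,
) -> KmerCounts:
    """Exact-match k-mer counting over synchronized read pairs.

    A pair increments a member's count at most once, whether the match lies
    in the forward read, the reverse read, or both. By default each k-mer is
    also searched as its reverse complement (``search_reverse_complement=
    False`` restricts matching for strand-specific libraries).
    """
    probes = []
    for ks in kmer_sets:
        for key, kmer in ks.members.items():
            variants = [kmer]
            if search_reverse_complement:
                variants.append(revcomp(kmer))
            probes.append((ks.id, key, variants))

    counts: dict[str, dict[str, int]] = {ks.id: {k: 0 for k in ks.members} for ks in kmer_sets}
    total = 0
    for pair in pairs:
        r1, r2 = pair if isinstance(pair, tuple) else (pair.r1, pair.r2)
        total += 1
        for set_id, key, variants in probes:
            if any(v in r1 or v in r2 for v in variants):
                counts[set_id][key] += 1
    return KmerCounts(counts=counts, total_pairs=total)


def mce_rpm(counts: KmerCounts, kmer_sets: list[KmerSet]) -> dict[str, float]:
    """Reads-per-million per copy: detections / total pairs x 1e6 per set,
    averaged across the sets targeting the same copy."""
    if counts.total_pairs <= 0:
        raise ValueError("total_pairs must be > 0")
    per_copy: dict[str, list[float]] = {}
    for ks in kmer_sets:
        if ks.mode != "MCE":
            continue
        for copy_label, _ in ks.members.items():
            rpm = counts.counts[ks.id][copy_label] / counts.total_pairs * 1_000_000
            per_copy.setdefault(copy_label, []).append(rpm)
    return {cp: float(np.mean(v)) for cp, v in per_copy.items()}


# ---------------------------------------------------------------------------
# allele-specific expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AseResult:
    proportion_allele1: float | None
    per_set: dict[str, float]
    qc_pass: bool
    qc_reason: str
    n_sets_used: int


def ase_proportion(
    counts: KmerCounts,
    kmer_sets: list[KmerSet],
    target: str,
    allele1: str | None = None,
    min_total_reads: int = 100,
) -> AseResult:
    """Allele-1 expression proportion for one target copy, with QC.

    QC requires at least one read from each allele, ``min_total_reads``
    total reads, and every k-mer set for the copy detected. The proportion
    is allele1/(allele1+allele2) per set, averaged across sets. QC failure
    is a value, not an exception.
    """
    sets = [ks for ks in kmer_sets if ks.mode == "ASE" and ks.target == target]
    if not sets:
        return AseResult(None, {}, False, "no ASE k-mer sets for target", 0)
    alleles = sorted(sets[0].members)
    a1 = allele1 if allele1 is not None else alleles[0]
    a2 = next(a for a in alleles if a != a1)

    tot1 = sum(counts.counts[ks.id][a1] for ks in sets)
    tot2 = sum(counts.counts[ks.id][a2] for ks in sets)
    if tot1 + tot2 < min_total_reads:
        return AseResult(None, {}, False, "min total reads", 0)
    if tot1 == 0 or tot2 == 0:
        return AseResult(None, {}, False, "missing allele", 0)
    undetected = [
        ks.id for ks in sets if sum(counts.counts[ks.id].values()) == 0
    ]
    if undetected:
        return AseResult(None, {}, False, "k-mer set undetected", 0)

    per_set = {}
    for ks in sets:
        c1, c2 = counts.counts[ks.id][a1], counts.counts[ks.id][a2]
        per_set[ks.id] = c1 / (c1 + c2)
    return AseResult(
        proportion_allele1=float(np.mean(list(per_set.values()))),
        per_set=per_set,
        qc_pass=True,
        qc_reason="",
        n_sets_used=len(per_set),
    )


def expected_allele_proportion(copies_allele1: float, copies_allele2: float) -> float:
    """Allele-1 expression proportion expected under strictly
    copy-proportional expression: c1 / (c1 + c2).

    E.g. a diploid carrying three target-gene copies on one haplotype and one
    on the other predicts 0.75 if every copy is expressed equally.
    """
    if copies_allele1 < 0 or copies_allele2 < 0 or copies_allele1 + copies_allele2 == 0:
        raise ValueError("copy numbers must be non-negative and not both zero")
    return copies_allele1 / (copies_allele1 + copies_allele2)


def ase_test(proportions, mu: float = 0.5, exact_max_n: int = 15):
    """One-sample Wilcoxon signed-rank test of ASE proportions against mu.

    Exact null distribution for n <= ``exact_max_n`` (after dropping values
    equal to mu), normal approximation otherwise; two-sided. Degenerate
    inputs (a single replicate, or all values at mu) return p = 1 with a
    warning rather than failing.
    """
    x = np.asarray(proportions, dtype=float)
    if len(x) < 1 or np.any(~np.isfinite(x)):
        raise ValueError("need >= 1 finite proportions")
    diffs = x - mu
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        warnings.warn("all proportions equal mu; test is uninformative")
        return 1.0
    if len(nonzero) == 1:
        warnings.warn("a single informative replicate; test is uninformative")
        return 1.0
    method = "exact" if len(nonzero) <= exact_max_n else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=method)
    return float(res.pvalue)


def ase_group_test(proportions_a, proportions_b, alternative: str = "two-sided"):
    """Two-sample Wilcoxon rank-sum comparison of ASE between conditions
    (e.g. rearing temperatures)."""
    res = stats.mannwhitneyu(
        np.asarray(proportions_a, dtype=float),
        np.asarray(proportions_b, dtype=float),
        alternative=alternative,
        method="auto",
    )
    return float(res.pvalue)
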