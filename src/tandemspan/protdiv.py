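"""Protein-level divergence among gene copies and between ecotypes.

Given aligned amino-acid sequences of every cluster copy from multiple
populations, this module quantifies: pairwise percent identity; positions at
which all freshwater sequences differ from all marine sequences (residue-set
disjointness per column — the strictest reading of "changed in all
freshwater"); enrichment of those divergent sites in a protein domain by an
exact hypergeometric upper-tail test; and coding-sequence integrity calls
(nonsense or frameshift truncation, in-frame deletion) against a reference
CDS.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "ProteinSet",
    "DomainInterval",
    "EnrichmentResult",
    "IntegrityStatus",
    "pairwise_identity",
    "ecotype_divergent_sites",
    "domain_enrichment",
    "cds_integrity",
]

GAPS = set("-.")


@dataclass(frozen=True)
class ProteinSet:
    """Aligned amino-acid sequences keyed by (population, copy label)."""

    sequences: dict[tuple[str, str], str]
    ecotype: dict[str, str]  # population -> marine / freshwater

    def __post_init__(self):
        if len({len(s) for s in self.sequences.values()}) != 1:
            raise ValueError("aligned sequences must have equal length")
        missing = {p for p, _ in self.sequences} - set(self.ecotype)
        if missing:
            raise ValueError(f"populations without ecotype labels: {sorted(missing)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def group(self, copy_label: str, ecotype: str) -> list[str]:
        return [
            seq
            for (pop, cp), seq in self.sequences.items()
            if cp == copy_label and self.ecotype[pop] == ecotype
        ]

    def most_abundant(self, copy_labels) -> str:
        """The modal sequence among the given copies — the reference against
        which per-sequence differences are reported."""
        from collections import Counter

        seqs = [
            s for (_, cp), s in self.sequences.items() if cp in set(copy_labels)
        ]
        if not seqs:
            raise ValueError("no sequences for the given copy labels")
        return Counter(seqs).most_common(1)[0][0]


@dataclass(frozen=True)
class DomainInterval:
    """A protein domain in 1-based inclusive residue coordinates."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError("require 1 <= start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos_1based: int) -> bool:
        return self.start <= pos_1based <= self.end


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over columns where neither sequence has a gap."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    comparable = ident = 0
    for a, b in zip(seq_a, seq_b):
        if a in GAPS or b in GAPS:
            continue
        comparable += 1
        ident += a == b
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns")
    return 100.0 * ident / comparable


def ecotype_divergent_sites(
    pset: ProteinSet, copy_label: str
) -> tuple[list[int], dict[tuple[str, str], list[int]]]:
    """Positions (1-based) where the freshwater and marine residue sets are
    disjoint for the given copy, plus per-sequence differences vs the most
    abundant freshwater sequence.

    A column qualifies only if *every* freshwater sequence differs from
    *every* marine sequence there; gap columns are excluded.
    """
    fresh = pset.group(copy_label, "freshwater")
    marine = pset.group(copy_label, "marine")
    if not fresh or not marine:
        raise ValueError(f"both ecotype groups must be non-empty for {copy_label!r}")
    divergent = []
    for c in range(pset.length):
        fw = {s[c] for s in fresh}
        mr = {s[c] for s in marine}
        if (fw | mr) & GAPS:
            continue
        if fw.isdisjoint(mr):
            divergent.append(c + 1)

    ref = pset.most_abundant([copy_label])
    per_seq = {}
    for (pop, cp), seq in pset.sequences.items():
        if cp != copy_label:
            continue
        per_seq[(pop, cp)] = [
            c + 1
            for c, (a, b) in enumerate(zip(seq, ref))
            if a != b and a not in GAPS and b not in GAPS
        ]
    return divergent, per_seq


@dataclass(frozen=True)
class EnrichmentResult:
    N: int  # protein length
    K: int  # domain length
    n: int  # divergent sites
    k: int  # divergent sites inside the domain
    p_upper: float

    def __post_init__(self):
        if self.k > min(self.n, self.K):
            raise ValueError("k cannot exceed min(n, K)")
        if not 0.0 <= self.p_upper <= 1.0:
            raise ValueError("p must be in [0, 1]")


def domain_enrichment(
    divergent_positions, domain: DomainInterval, protein_len: int
) -> EnrichmentResult:
    """Exact hypergeometric upper-tail test of divergent sites in a domain.

    With N = protein length, K = domain length, n = number of divergent
    sites and k = sites falling inside the domain, p = P(X >= k) for
    X ~ Hypergeometric(N, K, n).
    """
    positions = sorted(set(int(p) for p in divergent_positions))
    if any(p < 1 or p > protein_len for p in positions):
        raise ValueError("divergent positions must lie within [1, protein_len]")
    if domain.end > protein_len:
        raise ValueError("domain extends beyond the protein")
    n = len(positions)
    k = sum(domain.contains(p) for p in positions)
    p_upper = float(stats.hypergeom.sf(k - 1, protein_len, domain.length, n))
    return EnrichmentResult(
        N=protein_len, K=domain.length, n=n, k=k, p_upper=p_upper
    )


@dataclass(frozen=True)
class IntegrityStatus:
    status: str  # intact / nonsense-truncated / frameshift-truncated / in-frame-deletion
    truncation_residue: int | None = None  # 1-based residue of the premature stop

    def __post_init__(self):
        truncated = self.status in ("nonsense-truncated", "frameshift-truncated")
        if truncated != (self.truncation_residue is not None):
            raise ValueError("truncation position present iff truncated")


def _first_internal_stop(cds: str) -> int | None:
    """1-based codon index of the first internal stop, ignoring a terminal
    stop codon on a complete frame."""
    n_codons = len(cds) // 3
    aa = str(Seq(cds[: n_codons * 3]).translate())
    stop = aa.find("*")
    if stop == -1:
        return None
    if stop == n_codons - 1 and len(cds) % 3 == 0:
        return None  # the natural terminal stop
    return stop + 1


def cds_integrity(cds: str, reference_cds: str) -> IntegrityStatus:
    """Classify a coding sequence against a reference frame.

    An internal stop codon is a nonsense truncation at that residue. A
    length difference not divisible by 3 is a frameshift, truncating at the
    first out-of-frame stop. A clean multiple-of-3 deletion without internal
    stops is an in-frame deletion; otherwise the CDS is intact.
    """
    cds = cds.upper()
    reference_cds = reference_cds.upper()
    if len(reference_cds) % 3 != 0:
        raise ValueError("reference CDS length must be a multiple of 3")
    if not cds:
        raise ValueError("empty CDS")

    frameshift = (len(cds) - len(reference_cds)) % 3 != 0
    stop = _first_internal_stop(cds)
    if frameshift:
        # report the stop the shifted frame runs into (end of sequence if none)
        residue = stop if stop is not None else len(cds) // 3
        return IntegrityStatus(status="frameshift-truncated", truncation_residue=residue)
    if stop is not None:
        return IntegrityStatus(status="nonsense-truncated", truncation_residue=stop)
    if len(cds) < len(reference_cds):
        return IntegrityStatus(status="in-frame-deletion")
    return IntegrityStatus(status="intact")
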