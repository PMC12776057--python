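"""Synthetic tandem-duplication haplotypes, diploid genomes, and read sets.

This module generates the ground-truth material the rest of the package is
exercised on: myosin-like gene clusters in which a duplication unit (carrying
a full copy of the expanded gene plus fragments of the two flanking genes) is
repeated in tandem 1-4 times, mimicking the 3- to 6-copy cluster haplotypes
observed in marine and freshwater stickleback.

The model, at toy scale:

* a shared ancestral backbone ``[flank] C1 [i] C2 [unit]xN SYT19-rest [flank]``
  where each duplication unit is ``C2-suffix | gap | C3 gene | gap |
  SYT19-prefix``;
* ecotype-diagnostic SNPs drawn once on the backbone, so a marine/freshwater
  pair built from the same seed differs at exactly the SNP positions;
* a breakpoint-repair (MMBIR-style) junction between consecutive units that
  fuses the SYT19 and C2 fragments and is planted with an exact number of
  bases of perfect (and optionally imperfect) microhomology between the two
  donor genes;
* intermediate units in 5- and 6-copy haplotypes that are mosaics of the
  first (A) and last (L) unit, switching from L-derived to A-derived sequence
  at a planted unequal-crossover position.

Every planted quantity is recorded in a :class:`HaplotypeTruth` so downstream
detectors can be validated by round trip.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import mutate_base, random_seq, revcomp

__all__ = [
    "HaplotypeSpec",
    "ClusterGeometry",
    "HaplotypeTruth",
    "ReadSimParams",
    "WeightedPool",
    "ReadPair",
    "LongRead",
    "build_base_haplotype",
    "build_haplotype",
    "expand_mmbir",
    "recombine_nahr",
    "simulate_paired_reads",
    "simulate_long_reads",
    "build_transcript_family",
]

ECOTYPES = ("marine", "freshwater")


# ---------------------------------------------------------------------------
# specs and truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeSpec:
    """Parameters of one synthetic cluster haplotype.

    Defaults are desk-scale stand-ins: 6 kb flanking genes and a 2 kb
    duplication unit in place of the real ~17.6 kb unit; all lengths scale.
    """

    ecotype: str = "freshwater"
    copy_count: int = 3
    gene_length_bp: int = 6000
    dup_region_length_bp: int = 2000
    intergenic_length_bp: int = 1000
    snp_divergence_rate: float = 0.005
    unit_divergence_rate: float = 0.01
    microhomology_len_bp: int = 4
    imperfect_microhomology_bp: int | None = None
    crossover_pos: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.ecotype not in ECOTYPES:
            raise ValueError(f"ecotype must be one of {ECOTYPES}, got {self.ecotype!r}")
        if not 3 <= self.copy_count <= 6:
            raise ValueError(f"copy_count must be in [3, 6], got {self.copy_count}")
        for name in ("gene_length_bp", "dup_region_length_bp", "intergenic_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.snp_divergence_rate < 1.0:
            raise ValueError("snp_divergence_rate must be in [0, 1)")
        if self.microhomology_len_bp < 0:
            raise ValueError("microhomology_len_bp must be >= 0")
        if self.microhomology_len_bp >= self.dup_region_length_bp:
            raise ValueError("microhomology_len_bp must be < dup_region_length_bp")
        imp = self.imperfect_microhomology_bp
        if imp is not None and imp < self.microhomology_len_bp:
            raise ValueError("imperfect_microhomology_bp must be >= microhomology_len_bp")
        if self.copy_count == 3 and self.crossover_pos is not None:
            raise ValueError("copy_count 3 requires crossover_pos absent")
        if self.crossover_pos is not None and not (
            0 <= self.crossover_pos < self.dup_region_length_bp
        ):
            raise ValueError("crossover_pos must lie in [0, dup_region_length_bp)")


@dataclass(frozen=True)
class ClusterGeometry:
    """Fixed coordinate layout of a cluster haplotype (0-based, half-open).

    ``a``/``b`` are the lengths of the C2-suffix and SYT19-prefix fragments
    inside the duplication unit; ``u0`` is the start of the first unit.
    """

    flank: int       # intergenic / outer flank length
    gene: int        # C1, C2, SYT19 gene length
    unit: int        # duplication unit length
    a: int           # C2 fragment inside unit
    b: int           # SYT19 fragment inside unit
    gap: int         # intra-unit intergenic gap
    c3: int          # C3 gene length inside unit

    @classmethod
    def from_spec(cls, spec: HaplotypeSpec) -> "ClusterGeometry":
        D = spec.dup_region_length_bp
        a = b = max(D // 8, 1)
        gap = max(D // 10, 1)
        c3 = D - a - b - 2 * gap
        if c3 <= 0:
            raise ValueError("dup_region_length_bp too small for unit layout")
        return cls(
            flank=spec.intergenic_length_bp,
            gene=spec.gene_length_bp,
            unit=D,
            a=a,
            b=b,
            gap=gap,
            c3=c3,
        )

    @property
    def c1_start(self) -> int:
        return self.flank

    @property
    def c2_start(self) -> int:
        return 2 * self.flank + self.gene

    @property
    def u0(self) -> int:
        # first unit begins `a` bases before the end of C2
        return self.c2_start + self.gene - self.a

    def syt19_start(self, n_units: int) -> int:
        return self.u0 + n_units * self.unit - self.b

    def total_length(self, n_units: int) -> int:
        return self.syt19_start(n_units) + self.gene + self.flank

    def unit_start(self, j: int) -> int:
        return self.u0 + j * self.unit

    def c3_interval(self, j: int) -> tuple[int, int]:
        s = self.unit_start(j) + self.a + self.gap
        return s, s + self.c3

    def flank_exclusion(self, spec: HaplotypeSpec) -> int:
        """Half-width of the window around unit boundaries kept free of SNPs
        and paralog divergence, so junction microhomology is planted cleanly."""
        imp = spec.imperfect_microhomology_bp or spec.microhomology_len_bp
        return max(24, imp + 8)


def _c3_labels(n_units: int) -> list[str]:
    """C3 copy labels in cluster order: first is A, last is L, middles B, C."""
    if n_units == 1:
        return ["C3A"]
    middles = [f"C3{chr(ord('B') + i)}" for i in range(n_units - 2)]
    return ["C3A", *middles, "C3L"]


@dataclass
class HaplotypeTruth:
    """A synthetic haplotype plus its planted ground truth."""

    spec: HaplotypeSpec
    geometry: ClusterGeometry
    ancestral: str
    snp_table: dict[int, tuple[str, str]]  # pos -> (marine base, freshwater base)
    n_units: int
    planted_microhomology_bp: int = 0
    planted_imperfect_bp: int = 0
    planted_crossover_pos: int | None = None
    planted_crossover_interval: tuple[int, int] | None = None

    # -- derived views -----------------------------------------------------

    @property
    def ecotype(self) -> str:
        return self.spec.ecotype

    @property
    def copy_count(self) -> int:
        return self.n_units + 2

    @property
    def sequence(self) -> str:
        """The haplotype sequence with this ecotype's SNP alleles applied."""
        which = 0 if self.ecotype == "marine" else 1
        seq = list(self.ancestral)
        for pos, alleles in self.snp_table.items():
            seq[pos] = alleles[which]
        return "".join(seq)

    @property
    def unit_intervals(self) -> list[tuple[str, int, int]]:
        g = self.geometry
        labels = _c3_labels(self.n_units)
        return [
            (lab, g.unit_start(j), g.unit_start(j) + g.unit)
            for j, lab in enumerate(labels)
        ]

    @property
    def copy_intervals(self) -> list[tuple[str, int, int]]:
        g = self.geometry
        out = [
            ("C1", g.c1_start, g.c1_start + g.gene),
            ("C2", g.c2_start, g.c2_start + g.gene),
        ]
        for j, lab in enumerate(_c3_labels(self.n_units)):
            s, e = g.c3_interval(j)
            out.append((lab, s, e))
        return out

    @property
    def junction_offsets(self) -> list[int]:
        g = self.geometry
        return [g.unit_start(j) for j in range(1, self.n_units)]

    def unit_seq(self, label: str) -> str:
        seq = self.sequence
        for lab, s, e in self.unit_intervals:
            if lab == label:
                return seq[s:e]
        raise KeyError(f"no duplication unit labeled {label!r}")

    def junction_context(self, junction_index: int = 0, flank_window: int = 60):
        """Donor context of a unit-unit junction, for microhomology analysis.

        The left donor is the full SYT19 gene (its prefix ends at the
        junction); the right donor is the full C2 gene (its suffix begins at
        the junction). Returns a :class:`tandemspan.mechinfer.JunctionContext`.
        """
        from .mechinfer import JunctionContext

        if not 0 <= junction_index < self.n_units - 1:
            raise IndexError("junction index out of range")
        g = self.geometry
        seq = self.sequence
        syt_s = g.syt19_start(self.n_units)
        left_donor = seq[syt_s : syt_s + g.gene]
        right_donor = seq[g.c2_start : g.c2_start + g.gene]
        return JunctionContext(
            junction_pos=self.junction_offsets[junction_index],
            left_donor=left_donor,
            left_offset=g.b,
            right_donor=right_donor,
            right_offset=g.gene - g.a,
            flank_window=flank_window,
        )


# ---------------------------------------------------------------------------
# haplotype construction
# ---------------------------------------------------------------------------

def _plant_microhomology(
    seq: list[str], spec: HaplotypeSpec, geom: ClusterGeometry, rng: np.random.Generator
) -> None:
    """Edit the C2/SYT19 donor flanks so the (future) unit-unit junction
    carries exactly the requested perfect and imperfect microhomology.

    In donor-relative coordinates d (d < 0 left of the junction, d >= 0
    right), the left donor base is SYT19[b + d] and the right donor base is
    C2[gene - a + d]. We copy SYT19 bases into C2 over the planted windows
    and force mismatches at the walls bounding them.
    """
    k = spec.microhomology_len_bp
    imp = spec.imperfect_microhomology_bp if spec.imperfect_microhomology_bp is not None else k
    if imp + 3 > min(geom.a, geom.b) or geom.a < 2:
        raise ValueError(
            "dup_region_length_bp too small for the requested microhomology plant"
        )
    syt_s = geom.syt19_start(1)          # base haplotype has one unit
    c2_bp = geom.c2_start + geom.gene - geom.a   # junction offset within genome, right donor
    syt_bp = syt_s + geom.b                      # ... left donor

    def left_base(d: int) -> str:
        return seq[syt_bp + d]

    def set_right(d: int, base: str) -> None:
        seq[c2_bp + d] = base

    def force_mismatch(d: int) -> None:
        if seq[c2_bp + d] == left_base(d):
            set_right(d, mutate_base(rng, left_base(d)))

    # perfect core: the k bases immediately left of the junction
    for d in range(-k, 0):
        set_right(d, left_base(d))
    # wall between core and imperfect extension (the one tolerated mismatch)
    force_mismatch(-k - 1)
    # imperfect extension: total window [-imp, 0) has exactly one mismatch
    for d in range(-imp, -k - 1):
        set_right(d, left_base(d))
    # outer walls: two consecutive mismatches stop any budget-1 window
    for d in (-imp - 1, -imp - 2, 0, 1):
        force_mismatch(d)


def build_base_haplotype(spec: HaplotypeSpec) -> HaplotypeTruth:
    """Deterministically generate the 3-copy ancestral cluster for `spec`.

    Marine and freshwater specs sharing a seed share the ancestral backbone
    and SNP table, so their sequences differ at exactly the SNP positions.
    """
    spec.validate()
    geom = ClusterGeometry.from_spec(spec)
    rng = np.random.default_rng(spec.seed)

    total = geom.total_length(1)
    seq = list(random_seq(rng, total))
    _plant_microhomology(seq, spec, geom, rng)

    # ecotype SNPs: uniform over the backbone, excluding junction-flank
    # windows so microhomology detection is independent of SNP noise
    fw = geom.flank_exclusion(spec)
    excluded = set()
    for edge in (geom.u0, geom.u0 + geom.unit):
        excluded.update(range(max(0, edge - fw), min(total, edge + fw)))
    candidates = np.array(sorted(set(range(total)) - excluded))
    n_snp = int(round(spec.snp_divergence_rate * total))
    n_snp = min(n_snp, len(candidates))
    snp_pos = rng.choice(candidates, size=n_snp, replace=False)
    snp_table: dict[int, tuple[str, str]] = {}
    for pos in sorted(int(p) for p in snp_pos):
        anc = seq[pos]
        snp_table[pos] = (anc, mutate_base(rng, anc))  # marine ancestral, freshwater derived

    truth = HaplotypeTruth(
        spec=spec,
        geometry=geom,
        ancestral="".join(seq),
        snp_table=snp_table,
        n_units=1,
        planted_microhomology_bp=spec.microhomology_len_bp,
        planted_imperfect_bp=(
            spec.imperfect_microhomology_bp
            if spec.imperfect_microhomology_bp is not None
            else spec.microhomology_len_bp
        ),
    )
    return truth


def _shift_snps(snp_table, insert_at: int, length: int) -> dict:
    return {
        (p if p < insert_at else p + length): al for p, al in snp_table.items()
    }


def _insert_last_unit(hap: HaplotypeTruth, rng: np.random.Generator) -> HaplotypeTruth:
    """Append a diverged copy of the last unit in tandem and return the
    updated truth. SNP entries inside the copied unit are duplicated so the
    marine/freshwater contrast stays confined to the SNP table."""
    geom = hap.geometry
    spec = hap.spec
    e = geom.unit_start(hap.n_units)  # end of current last unit
    src_start = e - geom.unit
    unit = list(hap.ancestral[src_start:e])

    snp_table = _shift_snps(hap.snp_table, e, geom.unit)
    src_snp_offsets = {p - src_start for p in hap.snp_table if src_start <= p < e}
    for p, al in hap.snp_table.items():
        if src_start <= p < e:
            snp_table[p + geom.unit] = al

    fw = geom.flank_exclusion(spec)
    n_div = int(round(spec.unit_divergence_rate * geom.unit))
    # avoid junction flanks and SNP columns so planted quantities stay clean
    candidates = np.array(sorted(set(range(fw, geom.unit - fw)) - src_snp_offsets))
    n_div = min(n_div, len(candidates))
    for off in rng.choice(candidates, size=n_div, replace=False):
        unit[off] = mutate_base(rng, unit[off])

    ancestral = hap.ancestral[:e] + "".join(unit) + hap.ancestral[e:]
    return dataclasses.replace(
        hap,
        ancestral=ancestral,
        snp_table=snp_table,
        n_units=hap.n_units + 1,
    )


def expand_mmbir(hap: HaplotypeTruth, microhomology_len_bp: int | None = None,
                 seed: int | None = None) -> HaplotypeTruth:
    """Add one duplication unit in tandem via a breakpoint-repair junction.

    The new junction fuses the SYT19 and C2 donor fragments and shares the
    microhomology planted in the donors at construction time. The new (last)
    unit carries substitution divergence at `spec.unit_divergence_rate`, so
    the first and last units are distinguishable downstream.
    """
    if hap.n_units < 1:
        raise ValueError("haplotype must have at least 3 copies")
    if microhomology_len_bp is not None and microhomology_len_bp != hap.planted_microhomology_bp:
        raise ValueError(
            "junction microhomology is a property of the donor flanks; requested "
            f"{microhomology_len_bp} bp but the haplotype was built with "
            f"{hap.planted_microhomology_bp} bp (set it in HaplotypeSpec)"
        )
    if hap.planted_microhomology_bp >= hap.geometry.unit:
        raise ValueError("microhomology length must be below the unit length")
    rng = np.random.default_rng(
        seed if seed is not None else hap.spec.seed + 7919 * hap.n_units
    )
    return _insert_last_unit(hap, rng)


def _identity_interval(a: str, b: str, x: int) -> tuple[int, int]:
    """Maximal interval of identity between equal-length strings containing
    position x (half-open)."""
    lo = x
    while lo > 0 and a[lo - 1] == b[lo - 1]:
        lo -= 1
    hi = x
    while hi < len(a) and a[hi] == b[hi]:
        hi += 1
    return lo, hi


def build_haplotype(spec: HaplotypeSpec) -> HaplotypeTruth:
    """Build a haplotype with `spec.copy_count` gene copies.

    3 copies: the ancestral single-unit cluster. 4 copies: one MMBIR-style
    expansion. 5-6 copies: intermediate units that are L-derived before
    `spec.crossover_pos` and A-derived after it, as unequal crossover between
    the first and last units would produce.
    """
    spec.validate()
    hap = build_base_haplotype(spec)
    if spec.copy_count == 3:
        return hap
    hap = expand_mmbir(hap)  # 4 copies: units [A, L]
    n_intermediates = spec.copy_count - 4
    if n_intermediates == 0:
        return hap
    if spec.crossover_pos is None:
        # expand by further breakpoint-repair duplications of the last unit
        for _ in range(n_intermediates):
            hap = expand_mmbir(hap)
        return hap
    geom = hap.geometry
    x = spec.crossover_pos
    unit_a = hap.ancestral[geom.u0 : geom.u0 + geom.unit]
    s_l = geom.unit_start(1)
    unit_l = hap.ancestral[s_l : s_l + geom.unit]
    # the intermediate unit an unequal A/L crossover at x would produce
    hybrid = unit_l[:x] + unit_a[x:]
    inserted = hybrid * n_intermediates
    ancestral = hap.ancestral[:s_l] + inserted + hap.ancestral[s_l:]
    snp_table = _shift_snps(hap.snp_table, s_l, len(inserted))
    # duplicate SNP entries carried by the copied segments of A and L
    for p, al in hap.snp_table.items():
        off = None
        if s_l <= p < s_l + x:              # L-derived prefix
            off = p - s_l
        elif geom.u0 + x <= p < geom.u0 + geom.unit:  # A-derived suffix
            off = p - geom.u0
        if off is not None:
            for j in range(n_intermediates):
                snp_table[s_l + j * geom.unit + off] = al
    hap = dataclasses.replace(
        hap,
        ancestral=ancestral,
        snp_table=snp_table,
        n_units=hap.n_units + n_intermediates,
    )
    lo, hi = _identity_interval(unit_a, unit_l, x)
    return dataclasses.replace(
        hap, planted_crossover_pos=x, planted_crossover_interval=(lo, hi)
    )


def recombine_nahr(
    hap1: HaplotypeTruth,
    hap2: HaplotypeTruth,
    pairing: tuple[str, str],
    crossover_pos: int,
) -> tuple[HaplotypeTruth, HaplotypeTruth]:
    """Unequal crossover between misaligned units of two haplotypes.

    Pairing ``(label1, label2)`` aligns unit `label1` of `hap1` with unit
    `label2` of `hap2`; exchange happens `crossover_pos` bases into the
    paired units. Returns ``(duplication_product, deletion_product)`` —
    total copy number is conserved. The new intermediate unit of the
    duplication product is hap2-unit-derived before the crossover and
    hap1-unit-derived after it (5' L-like / 3' A-like when C3A is paired
    with C3L).
    """
    if hap1.geometry != hap2.geometry:
        raise ValueError("haplotypes must share the same cluster geometry")
    if hap1.ecotype != hap2.ecotype:
        raise ValueError("recombination bookkeeping requires a shared ecotype")
    geom = hap1.geometry
    if not 0 <= crossover_pos < geom.unit:
        raise ValueError("crossover_pos outside the duplication unit")

    def unit_index(hap: HaplotypeTruth, label: str) -> int:
        labels = _c3_labels(hap.n_units)
        if label not in labels:
            raise ValueError(f"no unit labeled {label!r} in haplotype")
        return labels.index(label)

    i1 = unit_index(hap1, pairing[0])
    i2 = unit_index(hap2, pairing[1])
    x = crossover_pos
    cut1 = geom.unit_start(i1) + x
    cut2 = geom.unit_start(i2) + x

    def make_product(pre: HaplotypeTruth, pre_cut: int, post: HaplotypeTruth,
                     post_cut: int, n_units: int) -> HaplotypeTruth:
        ancestral = pre.ancestral[:pre_cut] + post.ancestral[post_cut:]
        shift = pre_cut - post_cut
        snps = {p: al for p, al in pre.snp_table.items() if p < pre_cut}
        snps.update(
            {p + shift: al for p, al in post.snp_table.items() if p >= post_cut}
        )
        new_spec = dataclasses.replace(
            pre.spec, copy_count=n_units + 2, crossover_pos=None
        )
        return dataclasses.replace(
            pre,
            spec=new_spec,
            ancestral=ancestral,
            snp_table=snps,
            n_units=n_units,
            planted_crossover_pos=x,
            planted_crossover_interval=None,
        )

    n_del = i1 + (hap2.n_units - i2)
    n_dup = i2 + (hap1.n_units - i1)
    deletion = make_product(hap1, cut1, hap2, cut2, n_del)
    duplication = make_product(hap2, cut2, hap1, cut1, n_dup)

    # the identity interval around the exchange point, measured between the
    # two paired donor units as downstream analyses see them
    u1 = hap1.sequence[geom.unit_start(i1) : geom.unit_start(i1) + geom.unit]
    u2 = hap2.sequence[geom.unit_start(i2) : geom.unit_start(i2) + geom.unit]
    interval = _identity_interval(u1, u2, x)
    duplication = dataclasses.replace(
        duplication, planted_crossover_interval=interval
    )
    deletion = dataclasses.replace(deletion, planted_crossover_interval=interval)
    if duplication.n_units < deletion.n_units:
        duplication, deletion = deletion, duplication
    return duplication, deletion


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimParams:
    """Short paired-end read simulation parameters.

    Defaults follow the calibration setup used for depth interpretation:
    76 bp paired reads, fragment length 150 +/- 50 bp, 8x depth.
    """

    read_len_bp: int = 76
    frag_mu_bp: float = 150.0
    frag_sd_bp: float = 50.0
    per_base_error: float = 0.0
    depth_x: float | None = 8.0
    n_pairs: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.read_len_bp <= 0:
            raise ValueError("read_len_bp must be > 0")
        if self.read_len_bp > self.frag_mu_bp:
            raise ValueError("read_len_bp must not exceed frag_mu_bp")
        if not 0.0 <= self.per_base_error < 1.0:
            raise ValueError("per_base_error must be in [0, 1)")
        if (self.depth_x is None) == (self.n_pairs is None):
            raise ValueError("exactly one of depth_x and n_pairs must be set")


@dataclass(frozen=True)
class WeightedPool:
    """Labeled sequences with sampling weights (expression or genome pool)."""

    entries: tuple[tuple[str, str, float], ...]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("pool must be non-empty")
        labels = [e[0] for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("pool labels must be unique")
        if any(e[2] < 0 for e in self.entries):
            raise ValueError("weights must be >= 0")
        if not any(e[2] > 0 for e in self.entries):
            raise ValueError("at least one weight must be > 0")

    @classmethod
    def of(cls, *entries: tuple[str, str, float]) -> "WeightedPool":
        return cls(tuple(entries))

    @property
    def total_length(self) -> int:
        return sum(len(e[1]) for e in self.entries)


@dataclass(frozen=True)
class ReadPair:
    name: str
    r1: str
    r2: str
    source: str
    frag_start: int
    frag_len: int


@dataclass(frozen=True)
class LongRead:
    name: str
    seq: str
    source: str
    truncated: bool


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = mutate_base(rng, out[i])
    return "".join(out)


def simulate_paired_reads(pool: WeightedPool, params: ReadSimParams) -> list[ReadPair]:
    """Simulate FR-oriented paired-end reads from a weighted sequence pool.

    Source sequences are chosen proportional to weight x length; fragment
    lengths are normal, truncated to [read_len, len(source)]; the inner mate
    is reverse-complemented; substitution errors are i.i.d. per base.
    """
    params.validate()
    rl = params.read_len_bp
    usable = [(lab, seq, w) for lab, seq, w in pool.entries if len(seq) >= rl]
    if not usable:
        raise ValueError("all pool sequences are shorter than read_len_bp")
    rng = np.random.default_rng(params.seed)

    if params.n_pairs is not None:
        n_pairs = params.n_pairs
    else:
        n_pairs = int(round(params.depth_x * pool.total_length / (2 * rl)))

    weights = np.array([w * len(seq) for _, seq, w in usable], dtype=float)
    probs = weights / weights.sum()
    choices = rng.choice(len(usable), size=n_pairs, p=probs)

    pairs: list[ReadPair] = []
    for i, idx in enumerate(choices):
        label, seq, _ = usable[idx]
        lo, hi = rl, len(seq)
        fl = None
        for _ in range(64):
            draw = rng.normal(params.frag_mu_bp, params.frag_sd_bp)
            if lo <= draw <= hi:
                fl = int(round(draw))
                break
        if fl is None:
            fl = int(np.clip(round(params.frag_mu_bp), lo, hi))
        fl = min(max(fl, lo), hi)
        start = int(rng.integers(0, len(seq) - fl + 1))
        frag = seq[start : start + fl]
        r1 = _apply_errors(frag[:rl], rng, params.per_base_error)
        r2 = _apply_errors(revcomp(frag)[:rl], rng, params.per_base_error)
        pairs.append(
            ReadPair(
                name=f"sim_{label}_{i}_{start}_{fl}",
                r1=r1,
                r2=r2,
                source=label,
                frag_start=start,
                frag_len=fl,
            )
        )
    return pairs


def build_transcript_family(
    copy_labels: Sequence[str] = ("C1", "C2", "C3"),
    length: int = 1200,
    copy_divergence: float = 0.01,
    allele_divergence: float = 0.005,
    seed: int = 0,
) -> dict[tuple[str, str], str]:
    """Gap-free exonic alignment of a paralog family for both ecotype alleles.

    All copies derive from one ancestral transcript. Each copy carries
    private substitutions at rate ``copy_divergence`` (both alleles — these
    are the copy-diagnostic columns), and each copy's freshwater allele
    carries further private substitutions at rate ``allele_divergence`` (the
    allele-diagnostic columns). Rows are keyed (copy, allele) with alleles
    ``marine`` / ``freshwater``, ready for k-mer design.
    """
    rng = np.random.default_rng(seed)
    base = random_seq(rng, length)
    rows: dict[tuple[str, str], str] = {}
    for label in copy_labels:
        n_copy = int(round(copy_divergence * length))
        n_allele = int(round(allele_divergence * length))
        pos = rng.choice(length, size=n_copy + n_allele, replace=False)
        copy_pos, allele_pos = pos[:n_copy], pos[n_copy:]
        shared = list(base)
        for p in copy_pos:
            shared[p] = mutate_base(rng, shared[p])
        fresh = list(shared)
        for p in allele_pos:
            fresh[p] = mutate_base(rng, fresh[p])
        rows[(label, "marine")] = "".join(shared)
        rows[(label, "freshwater")] = "".join(fresh)
    return rows


def simulate_long_reads(
    pool: WeightedPool, n: int, seed: int = 0, truncation_rate: float = 0.0
) -> list[LongRead]:
    """Emit n full-length copies of pool entries sampled proportional to
    weight, with optional 5'/3' truncation to exercise full-span filters."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= truncation_rate <= 1.0:
        raise ValueError("truncation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    weights = np.array([w for _, _, w in pool.entries], dtype=float)
    probs = weights / weights.sum()
    out: list[LongRead] = []
    for i in range(n):
        idx = int(rng.choice(len(pool.entries), p=probs))
        label, seq, _ = pool.entries[idx]
        truncated = bool(rng.random() < truncation_rate) and len(seq) > 1
        if truncated:
            cut = int(rng.integers(1, len(seq)))
            seq = seq[cut:] if rng.random() < 0.5 else seq[: len(seq) - cut]
        out.append(LongRead(name=f"lr_{label}_{i}", seq=seq, source=label,
                            truncated=truncated))
    return out
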