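"""Mutational-mechanism inference for tandem duplication clusters.

Two signatures are analysed:

* **Breakpoint microhomology** (MMBIR-style events): at a junction that fuses
  fragments of two otherwise non-homologous donor genes, the length of the
  maximal window over which the donors are identical (perfect microhomology),
  and the maximal window containing that core with a small mismatch budget
  (imperfect microhomology).

* **Crossover windows** (NAHR-style events): an intermediate duplication unit
  produced by unequal crossover between the first (A) and last (L) unit is a
  5' L-like / 3' A-like mosaic. At alignment columns where A and L diverge,
  the intermediate's bases are labeled A or L and a single-changepoint model
  (L up to a point, A after) is fitted by exhaustive scan. The window between
  the last informative L-segment column and the first A-segment column bounds
  the putative exchange point; residual mismatches are flagged as putative
  gene-conversion tracts.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "JunctionContext",
    "MicrohomologyResult",
    "DivergentColumn",
    "CrossoverWindow",
    "junction_microhomology",
    "divergent_columns",
    "classify_intermediate",
    "strip_gap_columns",
    "infer_crossover_window",
    "crossover_analysis",
    "compare_crossovers",
]


# ---------------------------------------------------------------------------
# junction microhomology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionContext:
    """Donor context of a fusion junction.

    ``left_donor[left_offset]`` is the first donor base *after* the junction
    in the left donor's own coordinates (its prefix up to the offset lies left
    of the junction); symmetrically, ``right_donor[right_offset:]`` is the
    sequence the junction switches into. ``flank_window`` bounds the scan on
    either side of the junction.
    """

    junction_pos: int
    left_donor: str
    left_offset: int
    right_donor: str
    right_offset: int
    flank_window: int = 60

    def validate(self) -> None:
        if not self.left_donor or not self.right_donor:
            raise ValueError("donor sequences must be non-empty")
        if not 0 <= self.left_offset <= len(self.left_donor):
            raise ValueError("left_offset outside left donor")
        if not 0 <= self.right_offset <= len(self.right_donor):
            raise ValueError("right_offset outside right donor")
        if self.flank_window < 1:
            raise ValueError("flank_window must be >= 1")


@dataclass(frozen=True)
class MicrohomologyResult:
    perfect_len: int
    imperfect_len: int
    mismatch_budget: int
    window: tuple[int, int]  # imperfect window in junction-relative offsets


def junction_microhomology(
    ctx: JunctionContext, mismatch_budget: int = 1
) -> MicrohomologyResult:
    """Measure perfect and imperfect microhomology shared by the two donors
    across a junction.

    Donor bases are compared at matched junction-relative offsets d (d < 0
    left of the junction, d >= 0 right of it). ``perfect_len`` is the length
    of the maximal run of identity containing the junction point;
    ``imperfect_len`` is the length of the maximal window that contains the
    perfect core and spans the junction with at most ``mismatch_budget``
    mismatches, found by exhaustive window scan over the flank window.
    """
    ctx.validate()
    w = ctx.flank_window
    lo = -min(w, ctx.left_offset, ctx.right_offset)
    hi = min(
        w,
        len(ctx.left_donor) - ctx.left_offset,
        len(ctx.right_donor) - ctx.right_offset,
    )
    match = {
        d: ctx.left_donor[ctx.left_offset + d] == ctx.right_donor[ctx.right_offset + d]
        for d in range(lo, hi)
    }

    # perfect core: extend left from d=-1 and right from d=0
    a = 0
    while -a - 1 >= lo and match[-a - 1]:
        a += 1
    b = 0
    while b < hi and match[b]:
        b += 1
    perfect = a + b

    # imperfect: exhaustive scan over windows [i, j) with i <= -a, j >= b
    best_len, best_win = perfect, (-a, b)
    for i in range(lo, -a + 1):
        mism = 0
        for j in range(i, hi):
            if not match[j]:
                mism += 1
            if j + 1 >= b and mism <= mismatch_budget and (j + 1 - i) > best_len:
                best_len, best_win = j + 1 - i, (i, j + 1)
    return MicrohomologyResult(
        perfect_len=perfect,
        imperfect_len=best_len,
        mismatch_budget=mismatch_budget,
        window=best_win,
    )


# ---------------------------------------------------------------------------
# divergent columns and intermediate classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergentColumn:
    """An alignment column where the A and L duplication regions differ."""

    position: int  # column index in the gap-stripped alignment, 0-based
    a_base: str
    l_base: str


GAP_CHARS = set("-.")


def divergent_columns(
    alignment: dict[str, str], a_row: str = "A", l_row: str = "L"
) -> list[DivergentColumn]:
    """Columns where the A row differs from the L row.

    Columns containing a gap in any row are removed first (positions are
    reported in the gap-stripped coordinate system). Columns where only
    intermediate rows vary are uninformative and do not qualify.
    """
    for row in (a_row, l_row):
        if row not in alignment:
            raise ValueError(f"alignment is missing required row {row!r}")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    (length,) = lengths
    rows = list(alignment.values())
    out: list[DivergentColumn] = []
    pos = 0
    for c in range(length):
        if any(r[c] in GAP_CHARS for r in rows):
            continue  # gap columns are excluded and not counted
        a, l = alignment[a_row][c], alignment[l_row][c]
        if a != l:
            out.append(DivergentColumn(position=pos, a_base=a, l_base=l))
        pos += 1
    return out


def classify_intermediate(
    columns: list[DivergentColumn], intermediate: str
) -> list[tuple[int, str]]:
    """Label each divergent column by which allele the intermediate carries.

    ``intermediate`` is the intermediate row in the same gap-stripped
    coordinate system the columns were reported in (see
    :func:`strip_gap_columns`). Returns (position, label) pairs with label in
    {"A", "L", "other"}; "other" columns carry a third base and are excluded
    from the changepoint fit downstream.
    """
    labels = []
    for col in columns:
        base = intermediate[col.position]
        if base == col.a_base:
            lab = "A"
        elif base == col.l_base:
            lab = "L"
        else:
            lab = "other"
        labels.append((col.position, lab))
    return labels


def strip_gap_columns(alignment: dict[str, str]) -> dict[str, str]:
    """Remove every column that contains a gap in any row."""
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    rows = list(alignment.values())
    keep = [
        c for c in range(lengths.pop()) if not any(r[c] in GAP_CHARS for r in rows)
    ]
    return {k: "".join(v[c] for c in keep) for k, v in alignment.items()}


# ---------------------------------------------------------------------------
# crossover-window inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossoverWindow:
    """The interval bounding a putative unequal-crossover exchange point."""

    lo: int
    hi: int
    changepoints: tuple[int, ...]  # optimal split indices (count of L-side labels)
    mismatches: int                # residual label mismatches at the optimum
    conversion_positions: tuple[int, ...]  # positions deviating from the fit
    degenerate: bool = False       # all-L or all-A label sequence
    non_canonical: bool = False    # A-then-L orientation fits strictly better


def _changepoint_costs(labels: list[str]) -> list[int]:
    """cost[c] = mismatches of the model (first c labels L, rest A)."""
    n = len(labels)
    costs = []
    prefix_a = [0] * (n + 1)  # number of A labels among the first i
    for i, lab in enumerate(labels):
        prefix_a[i + 1] = prefix_a[i] + (lab == "A")
    total_a = prefix_a[n]
    for c in range(n + 1):
        # mismatches: A's in the L segment + L's in the A segment
        costs.append(prefix_a[c] + (n - c) - (total_a - prefix_a[c]))
    return costs


def infer_crossover_window(labeled: list[tuple[int, str]]) -> CrossoverWindow:
    """Fit the single-changepoint L-to-A model to ordered (position, label)
    pairs by exhaustive scan over all split points.

    Labels other than A/L are ignored. Ties: the window is the union over all
    optimal changepoints. An all-L or all-A sequence yields a degenerate
    window at the corresponding end; a sequence that fits the reversed
    (A-then-L) model strictly better is flagged non-canonical.
    """
    informative = [(p, lab) for p, lab in labeled if lab in ("A", "L")]
    if len(informative) < 2:
        raise ValueError("need at least 2 informative labels")
    informative.sort()
    positions = [p for p, _ in informative]
    labels = [lab for _, lab in informative]
    n = len(labels)

    costs = _changepoint_costs(labels)
    best = min(costs)
    optima = [c for c, cost in enumerate(costs) if cost == best]

    rev_costs = _changepoint_costs(["A" if l == "L" else "L" for l in labels])
    non_canonical = min(rev_costs) < best

    degenerate = 0 in optima or n in optima
    c_lo, c_hi = min(optima), max(optima)
    # window between the last informative column of the L segment and the
    # first informative column of the A segment, union over optimal splits
    lo = positions[c_lo - 1] if c_lo > 0 else positions[0]
    hi = positions[c_hi] if c_hi < n else positions[-1]
    if lo > hi:
        lo, hi = hi, lo

    # residual mismatches at the primary optimum (smallest optimal split)
    c = c_lo
    conversion = tuple(
        positions[i]
        for i in range(n)
        if (labels[i] == "A") == (i < c)
    )
    return CrossoverWindow(
        lo=lo,
        hi=hi,
        changepoints=tuple(optima),
        mismatches=best,
        conversion_positions=conversion,
        degenerate=degenerate,
        non_canonical=non_canonical,
    )


def crossover_analysis(
    alignment: dict[str, str], a_row: str = "A", l_row: str = "L"
) -> dict[str, CrossoverWindow]:
    """End-to-end crossover inference for every intermediate row.

    Strips gap columns, extracts A/L divergent columns, classifies each
    intermediate row, and fits the changepoint model per intermediate.
    """
    stripped = strip_gap_columns(alignment)
    columns = divergent_columns(stripped, a_row=a_row, l_row=l_row)
    out = {}
    for row, seq in stripped.items():
        if row in (a_row, l_row):
            continue
        labels = classify_intermediate(columns, seq)
        out[row] = infer_crossover_window(labels)
    return out


def compare_crossovers(
    windows: dict[str, tuple[int, int]]
) -> tuple[list[set[str]], int]:
    """Group assemblies whose crossover windows overlap.

    Windows must share one alignment coordinate system. Returns the groups
    (connected components under interval overlap) and their count — the
    minimum number of independent expansion events consistent with the data.
    """
    if not windows:
        return [], 0
    for name, (lo, hi) in windows.items():
        if lo >= hi:
            raise ValueError(f"window for {name!r} is empty or inverted")
    names = sorted(windows, key=lambda k: windows[k])
    groups: list[set[str]] = []
    current = {names[0]}
    reach = windows[names[0]][1]
    for name in names[1:]:
        lo, hi = windows[name]
        if lo < reach:  # half-open overlap
            current.add(name)
            reach = max(reach, hi)
        else:
            groups.append(current)
            current = {name}
            reach = hi
    groups.append(current)
    return groups, len(groups)
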