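#!/usr/bin/env python
"""Infer the mutational mechanisms behind copy-number expansion.

Part 1 (breakpoint repair): measure perfect and imperfect microhomology at
the fusion junction of each expanded cohort haplotype — every expansion
shares the junction planted with 4 bp perfect / 8 bp imperfect homology
between the two flanking-gene donors.

Part 2 (unequal crossover): generate reciprocal duplication/deletion
products by recombining two 4-copy haplotypes, then, for each 5/6-copy
assembly, label the intermediate unit's divergent columns as first-unit- or
last-unit-like, fit the single-changepoint model, and group assemblies by
crossover-window overlap to count independent expansion events.

Writes results/microhomology.tsv and results/crossover_windows.tsv.
"""

from pathlib import Path

from tandemspan import forge, mechinfer
from tandemspan.forge import HaplotypeSpec

SEED = 20260930

# 5/6-copy "assemblies": JADE/BEPA-like share one crossover, BLAU-like differs
ASSEMBLIES = [
    ("BEPA_like", 5, 900, SEED + 3),
    ("JADE_like", 5, 900, SEED + 4),
    ("BLAU_like", 6, 1400, SEED + 5),
]


def main() -> None:
    Path("results").mkdir(exist_ok=True)

    # --- junction microhomology ------------------------------------------
    rows = []
    for name, copies, crossover, seed in [("HULL_like", 4, None, SEED + 2)] + ASSEMBLIES:
        hap = forge.build_haplotype(
            HaplotypeSpec(
                ecotype="freshwater", copy_count=copies, crossover_pos=crossover,
                microhomology_len_bp=4, imperfect_microhomology_bp=8, seed=seed,
            )
        )
        res = mechinfer.junction_microhomology(hap.junction_context(0))
        rows.append((name, copies, res.perfect_len, res.imperfect_len))
    with open("results/microhomology.tsv", "w") as fh:
        fh.write("assembly\tcopy_count\tperfect_bp\timperfect_bp\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    print("junction microhomology (perfect/imperfect):")
    for name, copies, perf, imp in rows:
        print(f"  {name} ({copies}-copy): {perf}/{imp} bp")

    # --- reciprocal NAHR products ----------------------------------------
    h4 = forge.build_haplotype(
        HaplotypeSpec(ecotype="freshwater", copy_count=4, seed=SEED + 2)
    )
    dup, dele = forge.recombine_nahr(h4, h4, ("C3A", "C3L"), 900)
    print(
        f"\nunequal crossover of two 4-copy haplotypes -> reciprocal "
        f"{dup.copy_count}-copy duplication and {dele.copy_count}-copy deletion products"
    )

    # --- crossover windows per assembly ----------------------------------
    win_rows, windows = [], {}
    for name, copies, crossover, seed in ASSEMBLIES:
        hap = forge.build_haplotype(
            HaplotypeSpec(
                ecotype="freshwater", copy_count=copies, crossover_pos=crossover,
                microhomology_len_bp=4, imperfect_microhomology_bp=8, seed=seed,
            )
        )
        aln = {"A": hap.unit_seq("C3A"), "L": hap.unit_seq("C3L")}
        for lab, _, _ in hap.unit_intervals:
            if lab not in ("C3A", "C3L"):
                aln[lab[2:]] = hap.unit_seq(lab)  # B, C
        for row, win in mechinfer.crossover_analysis(aln).items():
            win_rows.append(
                (name, row, win.lo, win.hi, win.mismatches,
                 hap.planted_crossover_pos)
            )
        first = mechinfer.crossover_analysis(aln)["B"]
        windows[name] = (first.lo, first.hi if first.hi > first.lo else first.lo + 1)

    groups, n_events = mechinfer.compare_crossovers(windows)
    with open("results/crossover_windows.tsv", "w") as fh:
        fh.write("assembly\tintermediate\twindow_lo\twindow_hi\tmismatches"
                 "\tplanted_crossover\n")
        for row in win_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
        fh.write(f"# independent_expansion_events\t{n_events}\n")
        for g in groups:
            fh.write(f"# group\t{','.join(sorted(g))}\n")

    print("\ncrossover windows (intermediate units, L-to-A transitions):")
    for name, row, lo, hi, mism, planted in win_rows:
        print(f"  {name} {row}: [{lo}, {hi}) mismatches={mism} planted={planted}")
    print(f"minimum independent expansion events: {n_events}")
    for g in groups:
        print(f"  shared window: {sorted(g)}")


if __name__ == "__main__":
    main()
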