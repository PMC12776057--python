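#!/usr/bin/env python
"""Attribute full-length transcript reads to individual expanded gene copies.

Builds the informative-variant key over three near-identical copies
(C3A/C3B/C3L), simulates full-length reads at a 2:1:1 expression ratio with
a 20% truncation rate, and counts reads assignable under the full-span
requirement. Writes results/iso_attribution.tsv.
"""

from pathlib import Path

from tandemspan import forge, isoquant
from tandemspan.forge import WeightedPool

SEED = 20260930
N_READS = 5000
TRUNCATION_RATE = 0.2


def main() -> None:
    Path("results").mkdir(exist_ok=True)
    family = forge.build_transcript_family(
        copy_labels=("C3A", "C3B", "C3L"), seed=SEED + 400
    )
    copies = {cp: family[(cp, "freshwater")] for cp in ("C3A", "C3B", "C3L")}
    length = len(copies["C3A"])
    span = (length // 10, length - length // 10)
    key = isoquant.informative_variants(copies, span=span)
    print(
        f"{key.n_variants} informative variants distinguish the three copies "
        f"over span [{span[0]}, {span[1]})"
    )

    pool = WeightedPool.of(
        ("C3A", copies["C3A"], 2.0),
        ("C3B", copies["C3B"], 1.0),
        ("C3L", copies["C3L"], 1.0),
    )
    reads = forge.simulate_long_reads(
        pool, N_READS, seed=SEED + 401, truncation_rate=TRUNCATION_RATE
    )
    attr = isoquant.attribute_reads(reads, key)

    with open("results/iso_attribution.tsv", "w") as fh:
        fh.write("copy\treads\tproportion_of_assigned\n")
        for cp in sorted(attr.assigned):
            fh.write(f"{cp}\t{attr.assigned[cp]}\t{attr.proportions[cp]:.4f}\n")
        for reason, n in attr.unassigned.items():
            fh.write(f"unassigned:{reason}\t{n}\t.\n")

    print(f"assigned {attr.n_assigned}/{attr.total} reads "
          f"({attr.unassigned['not_spanning']} failed the full-span filter)")
    for cp in sorted(attr.assigned):
        print(f"  {cp}: {attr.proportions[cp]:.3f}")
    ratio = attr.proportions["C3A"] / max(
        attr.proportions["C3B"], attr.proportions["C3L"]
    )
    print(f"first-copy to next-copy expression ratio: {ratio:.2f} (simulated 2.0)")


if __name__ == "__main__":
    main()
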