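"""Attribution of full-length transcript reads to near-identical gene copies.

Short reads cannot distinguish tandem paralogs that differ at only a handful
of exonic positions, but a long read that fully spans every informative
variant can be assigned to a single copy. The procedure mirrors the
full-length-read analysis of expanded myosin clusters: build an ordered key
of the columns at which the copies differ within a spanning interval (the
exon 3-35 equivalent), require a read to cover the whole interval, and
assign it to the unique copy whose bases it matches at every key position.
Reads that do not span, match no copy, or match several are counted
unassigned with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp

__all__ = [
    "VariantKey",
    "AttributionCounts",
    "informative_variants",
    "attribute_reads",
]


@dataclass(frozen=True)
class VariantKey:
    """Ordered informative variants distinguishing all copies.

    ``profiles`` maps copy label -> bases at the key positions (in order);
    ``span`` is the [lo, hi) interval of the common coordinate system a read
    must fully cover; ``consensus`` is the span sequence with ``N`` at the
    variant positions, used for anchored placement of unaligned reads.
    """

    positions: tuple[int, ...]
    profiles: dict[str, str]
    span: tuple[int, int]
    consensus: str

    @property
    def n_variants(self) -> int:
        return len(self.positions)


def informative_variants(
    copy_sequences: dict[str, str], span: tuple[int, int] | None = None
) -> VariantKey:
    """Build the variant key from equal-length (gap-free) copy sequences.

    Every column within the span where at least two copies differ becomes a
    key position. Raises if some pair of copies is indistinguishable over
    the span, naming the pair.
    """
    if len(copy_sequences) < 2:
        raise ValueError("need at least 2 copies")
    lengths = {len(s) for s in copy_sequences.values()}
    if len(lengths) != 1:
        raise ValueError("copy sequences must have equal length")
    length = lengths.pop()
    lo, hi = span if span is not None else (0, length)
    if not (0 <= lo < hi <= length):
        raise ValueError("span outside the copy sequences")

    labels = sorted(copy_sequences)
    positions = [
        c
        for c in range(lo, hi)
        if len({copy_sequences[l][c] for l in labels}) > 1
    ]
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if all(copy_sequences[a][p] == copy_sequences[b][p] for p in positions):
                raise ValueError(
                    f"copies {a!r} and {b!r} are indistinguishable within the span"
                )
    profiles = {
        l: "".join(copy_sequences[l][p] for p in positions) for l in labels
    }
    template = copy_sequences[labels[0]]
    consensus = "".join(
        "N" if p in set(positions) else template[p] for p in range(lo, hi)
    )
    return VariantKey(
        positions=tuple(positions), profiles=profiles, span=(lo, hi), consensus=consensus
    )


@dataclass(frozen=True)
class AttributionCounts:
    assigned: dict[str, int]
    unassigned: dict[str, int]  # reasons: not_spanning / ambiguous / conflicting
    total: int

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def proportions(self) -> dict[str, float]:
        n = self.n_assigned
        if n == 0:
            return {k: 0.0 for k in self.assigned}
        return {k: v / n for k, v in self.assigned.items()}


def _anchor_offset(read: str, key: VariantKey) -> int | None:
    """Leftmost offset at which the read matches the span consensus exactly
    at every invariant position, or None."""
    span_len = key.span[1] - key.span[0]
    cons = key.consensus
    for off in range(len(read) - span_len + 1):
        if all(
            cons[j] == "N" or read[off + j] == cons[j] for j in range(span_len)
        ):
            return off
    return None


def attribute_reads(
    reads,
    key: VariantKey,
    require_full_span: bool = True,
    max_key_mismatch: int = 0,
    search_reverse_complement: bool = True,
) -> AttributionCounts:
    """Assign each read to the unique copy it matches at all key positions.

    Reads are placed by exact anchored search of the span interval (both
    orientations by default); pre-aligned inputs can instead supply
    ``(sequence, offset)`` tuples with the offset of span-start within the
    read (negative or None meaning the read does not reach the span). A read
    is assigned iff it covers the whole span and its bases at the key
    positions equal exactly one copy's profile, allowing up to
    ``max_key_mismatch`` mismatches (default 0 — no rescue of near-misses).
    """
    assigned = {label: 0 for label in key.profiles}
    unassigned = {"not_spanning": 0, "ambiguous": 0, "conflicting": 0}
    lo, hi = key.span
    span_len = hi - lo
    total = 0
    for item in reads:
        total += 1
        if isinstance(item, tuple):
            seq, off = item
            if off is None or off < 0 or off + span_len > len(seq):
                unassigned["not_spanning"] += 1
                continue
        else:
            seq = item.seq if hasattr(item, "seq") else str(item)
            off = _anchor_offset(seq, key)
            if off is None and search_reverse_complement:
                rc = revcomp(seq)
                off = _anchor_offset(rc, key)
                if off is not None:
                    seq = rc
            if off is None:
                # without a full anchored span there is nothing to key on,
                # regardless of require_full_span
                unassigned["not_spanning"] += 1
                continue
        observed = "".join(seq[off + p - lo] for p in key.positions)
        matches = [
            label
            for label, prof in key.profiles.items()
            if sum(a != b for a, b in zip(observed, prof)) <= max_key_mismatch
        ]
        if len(matches) == 1:
            assigned[matches[0]] += 1
        elif len(matches) > 1:
            unassigned["ambiguous"] += 1
        else:
            unassigned["conflicting"] += 1
    return AttributionCounts(assigned=assigned, unassigned=unassigned, total=total)
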