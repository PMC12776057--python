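"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def mutate_base(rng: np.random.Generator, base: str) -> str:
    """A base drawn uniformly from the three alternatives to `base`."""
    alts = [b for b in BASES if b != base]
    return alts[rng.integers(0, 3)]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
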