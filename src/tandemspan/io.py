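"""File I/O shared across stages: FASTA/FASTQ, BED, and truth tables.

Coordinates are 0-based half-open in BED output and internally; tabular
truth records state their convention in the header. FASTQ writing is
gzip-capable (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .forge import HaplotypeTruth, LongRead, ReadPair

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq_pairs",
    "read_fastq_pairs",
    "write_long_reads",
    "write_truth",
]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime keeps gzip output byte-identical across reruns
            import io as _io

            return _io.TextIOWrapper(
                gzip.GzipFile(path, "wb", mtime=0), encoding="ascii"
            )
        return gzip.open(path, mode)
    return open(path, mode.rstrip("t") if mode.endswith("t") else mode)


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with _open_text(path, "wt") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    with _open_text(path, "rt") as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fastq_pairs(pairs: list[ReadPair], path1, path2, quality: int = 35) -> None:
    """Write mates to two synchronized FASTQ files with a constant quality."""
    q = chr(quality + 33)
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.r1}\n+\n{q * len(p.r1)}\n")
            f2.write(f"@{p.name}/2\n{p.r2}\n+\n{q * len(p.r2)}\n")


def read_fastq_pairs(path1, path2):
    """Yield (r1, r2) sequence tuples from two synchronized FASTQ files."""
    with _open_text(path1, "rt") as f1, _open_text(path2, "rt") as f2:
        it1, it2 = SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")
        for rec1 in it1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise ValueError("mate files are desynchronized (file 2 shorter)")
            if rec1.id.rsplit("/", 1)[0] != rec2.id.rsplit("/", 1)[0]:
                raise ValueError(
                    f"mate files are desynchronized at {rec1.id} / {rec2.id}"
                )
            yield str(rec1.seq), str(rec2.seq)
        if next(it2, None) is not None:
            raise ValueError("mate files are desynchronized (file 1 shorter)")


def write_long_reads(reads: list[LongRead], path) -> None:
    write_fasta([(r.name, r.seq) for r in reads], path)


def write_truth(truth: HaplotypeTruth, prefix) -> None:
    """Write a haplotype's planted truth as FASTA + BED + TSV + JSON.

    ``<prefix>.fasta`` holds the sequence; ``<prefix>.bed`` the copy and unit
    intervals (0-based half-open); ``<prefix>.snps.tsv`` the ecotype SNP
    table; ``<prefix>.truth.json`` the planted scalar quantities.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    name = prefix.name
    write_fasta({name: truth.sequence}, prefix.with_suffix(".fasta"))
    with open(prefix.with_suffix(".bed"), "w") as fh:
        for label, s, e in truth.copy_intervals:
            fh.write(f"{name}\t{s}\t{e}\tgene:{label}\n")
        for label, s, e in truth.unit_intervals:
            fh.write(f"{name}\t{s}\t{e}\tunit:{label}\n")
    with open(str(prefix) + ".snps.tsv", "w") as fh:
        fh.write("# 0-based position\tmarine_base\tfreshwater_base\n")
        for pos in sorted(truth.snp_table):
            m, f = truth.snp_table[pos]
            fh.write(f"{pos}\t{m}\t{f}\n")
    meta = {
        "ecotype": truth.ecotype,
        "copy_count": truth.copy_count,
        "junction_offsets": truth.junction_offsets,
        "planted_microhomology_bp": truth.planted_microhomology_bp,
        "planted_imperfect_bp": truth.planted_imperfect_bp,
        "planted_crossover_pos": truth.planted_crossover_pos,
        "planted_crossover_interval": truth.planted_crossover_interval,
        "seed": truth.spec.seed,
    }
    with open(str(prefix) + ".truth.json", "w") as fh:
        json.dump(meta, fh, indent=2)
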