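"""End-to-end orchestration: configuration, staged execution, manifest.

A pipeline run forges a marine/freshwater haplotype pair plus read sets,
then exercises every analysis stage on them: depth calibration and diploid
copy calling, discriminating-k-mer expression (copy RPM and allele
proportion), full-span long-read attribution, and mechanism inference
(junction microhomology, crossover window). Outputs are TSV/FASTA/JSON files
under a run directory, listed with checksums in ``manifest.json``;
deterministic stages reproduce checksums on rerun with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import depthcnv, forge, io, isoquant, kmerquant, mechinfer

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_PROVENANCE"]

# the study convention each default encodes; written into the manifest
DEFAULT_PROVENANCE = {
    "read_len_bp": "76 bp paired-end reads (HiSeq2000-style simulation)",
    "frag_mu_bp": "mean fragment size 150 bp",
    "frag_sd_bp": "fragment size standard deviation 50 bp",
    "depth_x": "8x simulated depth for copy-number calibration",
    "kmer_k": "27-bp discriminating k-mers",
    "min_mapq": "minimum mapping quality 3 for depth accumulation",
    "ase_min_total_reads": "minimum 100 total allele-informative reads",
    "microhomology_bp": "4 bp perfect junction microhomology",
    "imperfect_microhomology_bp": "8 bp imperfect junction microhomology",
    "fresh_copy_count": "5-copy freshwater cluster haplotype",
    "marine_copy_count": "3-copy marine cluster haplotype",
    "iso_weights": "copy expression ratio 2:1:1 (first copy twice the others)",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; every field has a study-derived default."""

    seed: int = 0
    out_dir: str = "runs/demo"
    stages: tuple[str, ...] = ("forge", "depth", "kmer", "iso", "mech")

    # forge
    gene_length_bp: int = 6000
    dup_region_length_bp: int = 2000
    intergenic_length_bp: int = 1000
    marine_copy_count: int = 3
    fresh_copy_count: int = 5
    crossover_pos: int | None = 900
    microhomology_bp: int = 4
    imperfect_microhomology_bp: int = 8

    # reads
    read_len_bp: int = 76
    frag_mu_bp: float = 150.0
    frag_sd_bp: float = 50.0
    depth_x: float = 8.0

    # kmer
    kmer_k: int = 27
    rna_pairs: int = 20000
    ase_min_total_reads: int = 100

    # iso
    iso_reads: int = 2000
    iso_weights: tuple[float, float, float] = (2.0, 1.0, 1.0)

    # depth
    min_mapq: int = 3

    def validate(self) -> None:
        known = {"forge", "depth", "kmer", "iso", "mech"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValueError("no stages enabled")
        if "forge" not in self.stages and {"depth", "mech"} & set(self.stages):
            raise ValueError("depth and mech stages require the forge stage")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        if "iso_weights" in d:
            d = {**d, "iso_weights": tuple(d["iso_weights"])}
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    outputs: list[Path] = []

    def save_tsv(name: str, header: list[str], rows) -> Path:
        path = out / name
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(v) for v in row) + "\n")
        outputs.append(path)
        return path

    hap_m = hap_f = None
    if "forge" in config.stages:
        spec_m = forge.HaplotypeSpec(
            ecotype="marine",
            copy_count=config.marine_copy_count,
            gene_length_bp=config.gene_length_bp,
            dup_region_length_bp=config.dup_region_length_bp,
            intergenic_length_bp=config.intergenic_length_bp,
            microhomology_len_bp=config.microhomology_bp,
            imperfect_microhomology_bp=config.imperfect_microhomology_bp,
            seed=config.seed,
        )
        spec_f = dataclasses.replace(
            spec_m,
            ecotype="freshwater",
            copy_count=config.fresh_copy_count,
            crossover_pos=config.crossover_pos if config.fresh_copy_count >= 5 else None,
        )
        hap_m, hap_f = forge.build_haplotype(spec_m), forge.build_haplotype(spec_f)
        io.write_truth(hap_m, out / "marine")
        io.write_truth(hap_f, out / "freshwater")
        outputs += sorted(out.glob("marine*")) + sorted(out.glob("freshwater*"))
        results["forge"] = {
            "marine_copy_count": hap_m.copy_count,
            "freshwater_copy_count": hap_f.copy_count,
        }

    if "depth" in config.stages:
        params = forge.ReadSimParams(
            read_len_bp=config.read_len_bp,
            frag_mu_bp=config.frag_mu_bp,
            frag_sd_bp=config.frag_sd_bp,
            depth_x=config.depth_x,
            seed=config.seed + 1,
        )
        calib = {}
        base_spec = hap_m.spec
        for c in range(3, 7):
            calib[c] = [
                forge.build_haplotype(
                    dataclasses.replace(
                        base_spec,
                        ecotype="freshwater" if c > 3 else "marine",
                        copy_count=c,
                        crossover_pos=None,
                        seed=config.seed + 100 + c,
                    )
                )
            ]
        table = depthcnv.build_call_table(calib, params)
        save_tsv(
            "call_table.tsv",
            ["copy_count", "expected_normalized_depth", "provenance"],
            [
                (c, f"{d:.4f}", p)
                for (c, d), p in zip(table.entries, table.provenance)
            ],
        )
        diploid_params = dataclasses.replace(params, depth_x=config.depth_x / 2, seed=config.seed + 2)
        nd = depthcnv.diploid_normalized_depth(hap_m, hap_f, diploid_params)
        call, dist = depthcnv.call_diploid_total(nd.value, table)
        truth_total = hap_m.copy_count + hap_f.copy_count
        save_tsv(
            "depth_calls.tsv",
            ["sample", "normalized_depth", "mode", "called_total", "distance", "true_total"],
            [("marine_x_freshwater_F1", f"{nd.value:.4f}", nd.mode, call, f"{dist:.4f}", truth_total)],
        )
        results["depth"] = {
            "normalized_depth": nd.value,
            "called_total_copies": call,
            "true_total_copies": truth_total,
        }

    if "kmer" in config.stages:
        family = forge.build_transcript_family(seed=config.seed + 11)
        alignment = kmerquant.ParalogAlignment(rows=family)
        mce = kmerquant.design_kmers(alignment, "MCE", k=config.kmer_k)
        ase = kmerquant.design_kmers(alignment, "ASE", k=config.kmer_k, target="C3")
        # transcript-end screen: coverage decays at the ends, so k-mers
        # within 100 bp of a transcript end give noisy proportions
        mce = kmerquant.screen_kmers(mce, {}, min_end_distance=100)
        ase = kmerquant.screen_kmers(ase, {}, min_end_distance=100)
        # expression pool: freshwater carries 3 C3 copies vs 1 marine copy
        pool = forge.WeightedPool.of(
            ("C1_m", family[("C1", "marine")], 1.0),
            ("C1_f", family[("C1", "freshwater")], 1.0),
            ("C2_m", family[("C2", "marine")], 4.0),
            ("C2_f", family[("C2", "freshwater")], 4.0),
            ("C3_m", family[("C3", "marine")], 2.0),
            ("C3_f", family[("C3", "freshwater")], 6.0),
        )
        rna_params = forge.ReadSimParams(
            read_len_bp=config.read_len_bp,
            frag_mu_bp=config.frag_mu_bp,
            frag_sd_bp=config.frag_sd_bp,
            depth_x=None,
            n_pairs=config.rna_pairs,
            seed=config.seed + 12,
        )
        pairs = forge.simulate_paired_reads(pool, rna_params)
        io.write_fastq_pairs(pairs, out / "rna_R1.fastq.gz", out / "rna_R2.fastq.gz")
        outputs += [out / "rna_R1.fastq.gz", out / "rna_R2.fastq.gz"]
        counts = kmerquant.count_pairs([(p.r1, p.r2) for p in pairs], mce + ase)
        rpm = kmerquant.mce_rpm(counts, mce)
        ase_res = kmerquant.ase_proportion(
            counts, ase, "C3", allele1="freshwater",
            min_total_reads=config.ase_min_total_reads,
        )
        save_tsv(
            "kmer_sets.tsv",
            ["id", "mode", "target", "member", "kmer", "col_start", "col_end"],
            [
                (ks.id, ks.mode, ks.target or ".", key, kmer, *ks.source_columns)
                for ks in mce + ase
                for key, kmer in ks.members.items()
            ],
        )
        save_tsv(
            "expression.tsv",
            ["quantity", "value"],
            [(f"RPM_{cp}", f"{v:.2f}") for cp, v in sorted(rpm.items())]
            + [
                ("ASE_C3_freshwater", f"{ase_res.proportion_allele1:.4f}" if ase_res.qc_pass else "NA"),
                ("ASE_qc", "pass" if ase_res.qc_pass else ase_res.qc_reason),
            ],
        )
        results["kmer"] = {
            "n_mce_sets": len(mce),
            "n_ase_sets": len(ase),
            "rpm": rpm,
            "ase_c3_freshwater": ase_res.proportion_allele1,
            "ase_qc_pass": ase_res.qc_pass,
        }

    if "iso" in config.stages:
        iso_family = forge.build_transcript_family(
            copy_labels=("C3A", "C3B", "C3L"), seed=config.seed + 21
        )
        copies = {cp: iso_family[(cp, "freshwater")] for cp in ("C3A", "C3B", "C3L")}
        length = len(copies["C3A"])
        span = (length // 10, length - length // 10)
        key = isoquant.informative_variants(copies, span=span)
        pool = forge.WeightedPool.of(
            *[
                (cp, copies[cp], w)
                for cp, w in zip(("C3A", "C3B", "C3L"), config.iso_weights)
            ]
        )
        reads = forge.simulate_long_reads(pool, config.iso_reads, seed=config.seed + 22)
        io.write_long_reads(reads, out / "long_reads.fasta")
        outputs.append(out / "long_reads.fasta")
        attr = isoquant.attribute_reads(reads, key)
        save_tsv(
            "iso_attribution.tsv",
            ["copy", "reads", "proportion"],
            [
                (cp, attr.assigned[cp], f"{attr.proportions[cp]:.4f}")
                for cp in sorted(attr.assigned)
            ]
            + [(f"unassigned:{k}", v, ".") for k, v in attr.unassigned.items()],
        )
        results["iso"] = {
            "n_variants": key.n_variants,
            "proportions": attr.proportions,
            "unassigned": attr.unassigned,
        }

    if "mech" in config.stages:
        hap = hap_f if hap_f is not None and hap_f.n_units >= 2 else hap_m
        mh = mechinfer.junction_microhomology(hap.junction_context(0))
        rows = [
            ("perfect_microhomology_bp", mh.perfect_len),
            ("imperfect_microhomology_bp", mh.imperfect_len),
            ("planted_perfect_bp", hap.planted_microhomology_bp),
            ("planted_imperfect_bp", hap.planted_imperfect_bp),
        ]
        mech_out = {
            "perfect_microhomology_bp": mh.perfect_len,
            "imperfect_microhomology_bp": mh.imperfect_len,
        }
        if hap.n_units >= 3:
            aln = {
                "A": hap.unit_seq("C3A"),
                "L": hap.unit_seq("C3L"),
                "B": hap.unit_seq("C3B"),
            }
            win = mechinfer.crossover_analysis(aln)["B"]
            rows += [
                ("crossover_window_lo", win.lo),
                ("crossover_window_hi", win.hi),
                ("crossover_mismatches", win.mismatches),
                ("planted_crossover_pos", hap.planted_crossover_pos),
            ]
            mech_out["crossover_window"] = (win.lo, win.hi)
            mech_out["planted_crossover_pos"] = hap.planted_crossover_pos
        save_tsv("mechanism.tsv", ["quantity", "value"], rows)
        results["mech"] = mech_out

    manifest = {
        "config": dataclasses.asdict(config),
        "default_provenance": DEFAULT_PROVENANCE,
        "results": results,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in outputs if p.is_file()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
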