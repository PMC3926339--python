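"""Pipeline configuration and the end-to-end simulation driver.

A :class:`SimConfig` nests the per-module configs; a single global seed
deterministically derives every module's seed, so a full run is
reproducible from (inputs, config, seed) alone. Stage order is fixed:
SNV → indel → CNV (which must see the indel truth set to avoid boundary
collisions) → allele realization → read generation. Each run writes a
provenance manifest echoing the configuration, the seed and the package
version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cnv import CNVConfig, simulate_cnvs, write_cnv_bed, write_cnv_table
from .indels import IndelConfig, simulate_indels, write_indel_logs, write_indel_vcf
from .quality import QualityProfile
from .reads import ReadGenConfig, generate_reads
from .reference import ReferenceGenome, apply_variants, read_fasta, write_fasta
from .snv import SNVConfig, simulate_snvs, write_snv_log, write_snv_vcf


def derive_seed(global_seed: int, module: str) -> int:
    """Stable per-module seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{module}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SimConfig:
    reference: str | None = None
    outdir: str = "."
    seed: int = 0
    snv: SNVConfig | None = None
    indel: IndelConfig | None = None
    cnv: CNVConfig | None = None
    reads: ReadGenConfig | None = None
    profile_path: str | None = None
    write_allele_fasta: bool = True

    def __post_init__(self) -> None:
        # the global seed overrides any per-module seed so one integer
        # reproduces the whole run
        for name in ("snv", "indel", "cnv", "reads"):
            cfg = getattr(self, name)
            if cfg is not None:
                cfg.seed = derive_seed(self.seed, name)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        kwargs = {k: raw[k] for k in ("reference", "outdir", "seed", "profile_path",
                                      "write_allele_fasta") if k in raw}
        if "snv" in raw:
            kwargs["snv"] = SNVConfig(**(raw["snv"] or {}))
        if "indel" in raw:
            indel_raw = dict(raw["indel"] or {})
            kwargs["indel"] = IndelConfig(**indel_raw)
        if "cnv" in raw:
            kwargs["cnv"] = CNVConfig(**(raw["cnv"] or {}))
        if "reads" in raw:
            kwargs["reads"] = ReadGenConfig(**(raw["reads"] or {}))
        return cls(**kwargs)

    def manifest(self) -> dict:
        out = {"version": __version__, "seed": self.seed, "config": {}}
        for name in ("snv", "indel", "cnv", "reads"):
            cfg = getattr(self, name)
            if cfg is not None:
                out["config"][name] = asdict(cfg)
        out["config"]["reference"] = self.reference
        out["config"]["outdir"] = self.outdir
        return out


@dataclass
class PipelineResult:
    snvs: list = field(default_factory=list)
    indels: list = field(default_factory=list)
    cnvs: list = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    n_pairs: int = 0


def run_pipeline(config: SimConfig, genome: ReferenceGenome | None = None) -> PipelineResult:
    """Run the enabled stages in order and write all outputs + manifest."""
    if genome is None:
        if config.reference is None:
            raise ValueError("a reference path or an in-memory genome is required")
        genome = read_fasta(config.reference)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()

    if config.snv is not None:
        result.snvs = simulate_snvs(genome, config.snv)
        log = outdir / "snv_truth.tsv"
        write_snv_log(result.snvs, log)
        vcf = outdir / "snv_truth.vcf"
        write_snv_vcf(result.snvs, vcf, {c: len(s) for c, s in genome.chromosomes.items()})
        result.outputs["snv_log"] = str(log)
        result.outputs["snv_vcf"] = str(vcf)

    if config.indel is not None:
        result.indels = simulate_indels(genome, config.indel)
        log1 = outdir / "indel_truth_allele1.tsv"
        log2 = outdir / "indel_truth_allele2.tsv"
        write_indel_logs(result.indels, log1, log2)
        vcf = outdir / "indel_truth.vcf"
        write_indel_vcf(result.indels, vcf, genome)
        result.outputs["indel_log_allele1"] = str(log1)
        result.outputs["indel_log_allele2"] = str(log2)
        result.outputs["indel_vcf"] = str(vcf)

    if config.cnv is not None:
        result.cnvs = simulate_cnvs(genome, config.cnv, result.indels)
        table = outdir / "cnv_truth.tsv"
        bed = outdir / "cnv_truth.bed"
        write_cnv_table(result.cnvs, table)
        write_cnv_bed(result.cnvs, bed)
        result.outputs["cnv_table"] = str(table)
        result.outputs["cnv_bed"] = str(bed)

    needs_alleles = config.write_allele_fasta or config.reads is not None
    alleles = []
    if needs_alleles:
        for allele_index in (1, 2):
            per_chrom = apply_variants(
                genome, result.snvs, result.indels, result.cnvs, allele_index
            )
            alleles.extend(per_chrom.values())
        if config.write_allele_fasta:
            fasta = outdir / "alleles.fasta"
            write_fasta(alleles, fasta)
            result.outputs["allele_fasta"] = str(fasta)

    if config.reads is not None:
        if config.profile_path is None:
            raise ValueError("read generation requires profile_path")
        profile = QualityProfile.from_file(config.profile_path)
        r1 = outdir / "reads_1.fastq"
        r2 = outdir / "reads_2.fastq" if config.reads.paired else None
        result.n_pairs = generate_reads(alleles, profile, config.reads, r1, r2)
        result.outputs["reads_r1"] = str(r1)
        if r2 is not None:
            result.outputs["reads_r2"] = str(r2)

    manifest = config.manifest()
    manifest["outputs"] = result.outputs
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True, default=str)
        out.write("\n")
    result.outputs["manifest"] = str(manifest_path)
    return result
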