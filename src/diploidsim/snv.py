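"""Genome-wide SNV simulation.

SNVs are placed by a random walk along each chromosome whose step sizes are
Gaussian around the mean inter-SNV distance D_avg derived from the requested
SNV rate (D_avg = 1/rate, clamped to the 300-1000 bp range observed for
human polymorphism densities). A positional filter enforces a minimum
spacing between SNVs and placements inside N-regions are discarded rather
than relocated. The alternate base respects a configurable
transition/transversion (Ti/Tv) ratio — 2.1 by default, the genome-wide
human value; 0.5 corresponds to each alternative base being equally likely.
A configurable fraction of SNVs (default 20%) is heterozygous, assigned to
allele 1 or 2 by a fair coin.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .reference import ReferenceGenome

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class SNVConfig:
    """Tunable parameters of the SNV simulator."""

    snv_rate: float = 0.001  # fraction of genome carrying an SNV
    titv_ratio: float = 2.1  # expected transitions per transversion
    het_fraction: float = 0.20  # probability an SNV is heterozygous
    min_spacing: int = 15  # bases; closer pairs are filtered
    davg_lower: int = 300  # clamp bounds for the mean spacing
    davg_upper: int = 1000
    spacing_sd: float | None = None  # default D_avg / 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.snv_rate < 1:
            raise ValueError("snv_rate must be in (0, 1)")
        if self.titv_ratio <= 0:
            raise ValueError("titv_ratio must be > 0")
        if not 0 <= self.het_fraction <= 1:
            raise ValueError("het_fraction must be in [0, 1]")
        if self.min_spacing < 1:
            raise ValueError("min_spacing must be >= 1")
        if self.davg_lower > self.davg_upper:
            raise ValueError("davg_lower must be <= davg_upper")


@dataclass
class SNVRecord:
    chrom: str
    pos: int  # 1-based reference coordinate
    ref_base: str
    alt_base: str
    zygosity: str  # "het" | "hom"
    allele: int | str  # 1 | 2 | "both"
    is_transition: bool


def compute_davg(snv_rate: float, lower: int = 300, upper: int = 1000) -> int:
    """Mean inter-SNV distance for a requested rate, clamped to [lower, upper]."""
    if not 0 < snv_rate < 1:
        raise ValueError("snv_rate must be in (0, 1)")
    return int(min(max(round(1.0 / snv_rate), lower), upper))


def sample_snv_positions(
    chrom_length: int, cfg: SNVConfig, rng: np.random.Generator
) -> list[int]:
    """Random-walk SNV positions (1-based) with Normal(D_avg, sd) gaps.

    Each gap is rounded to an integer and floored at ``cfg.min_spacing``;
    the walk stops once it passes the chromosome end.
    """
    if chrom_length < 1:
        raise ValueError("chrom_length must be >= 1")
    davg = compute_davg(cfg.snv_rate, cfg.davg_lower, cfg.davg_upper)
    sd = cfg.spacing_sd if cfg.spacing_sd is not None else davg / 4.0
    positions: list[int] = []
    pos = 0
    while True:
        gap = int(round(rng.normal(davg, sd))) if sd > 0 else davg
        gap = max(gap, cfg.min_spacing)
        pos += gap
        if pos > chrom_length:
            break
        positions.append(pos)
    return positions


def positional_filter(positions: Sequence[int], min_spacing: int) -> list[int]:
    """Greedy left-to-right filter dropping positions closer than min_spacing
    to the last kept one. A gap exactly equal to min_spacing is kept."""
    kept: list[int] = []
    for p in positions:
        if not kept or p - kept[-1] >= min_spacing:
            kept.append(p)
    return kept


def n_region_filter(
    positions: Sequence[int], n_regions: Sequence[tuple[int, int]]
) -> list[int]:
    """Drop 1-based positions that fall inside any 0-based half-open N interval."""
    if not n_regions:
        return list(positions)
    starts = [iv[0] for iv in n_regions]
    kept = []
    for p in positions:
        z = p - 1
        i = bisect_right(starts, z) - 1
        if i >= 0 and z < n_regions[i][1]:
            continue
        kept.append(p)
    return kept


def choose_alt_base(
    ref_base: str, titv_ratio: float, rng: np.random.Generator
) -> tuple[str, bool]:
    """Alternate base under the Ti/Tv model.

    A transition is emitted with probability R/(R+1) so that the expected
    transition:transversion count ratio is R; the two transversion partners
    are equally likely otherwise.
    """
    if ref_base not in TRANSITION:
        raise ValueError(f"ref_base must be one of A/C/G/T, got {ref_base!r}")
    p_ti = titv_ratio / (titv_ratio + 1.0)
    if rng.random() < p_ti:
        return TRANSITION[ref_base], True
    tv = TRANSVERSIONS[ref_base]
    return tv[int(rng.integers(2))], False


def assign_zygosity(
    het_fraction: float, rng: np.random.Generator
) -> tuple[str, int | str]:
    """Draw (zygosity, allele): het with probability het_fraction, fair-coin allele."""
    if rng.random() < het_fraction:
        return "het", 1 + int(rng.integers(2))
    return "hom", "both"


def simulate_snvs(
    genome: ReferenceGenome,
    cfg: SNVConfig,
    rng: np.random.Generator | None = None,
) -> list[SNVRecord]:
    """Simulate SNVs over every chromosome: place, filter, mutate, assign zygosity."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    records: list[SNVRecord] = []
    for chrom, sequence in genome.chromosomes.items():
        positions = sample_snv_positions(len(sequence), cfg, rng)
        positions = positional_filter(positions, cfg.min_spacing)
        positions = n_region_filter(positions, genome.n_regions.get(chrom, []))
        for pos in positions:
            ref_base = sequence[pos - 1]
            alt_base, is_ti = choose_alt_base(ref_base, cfg.titv_ratio, rng)
            zygosity, allele = assign_zygosity(cfg.het_fraction, rng)
            records.append(
                SNVRecord(chrom, pos, ref_base, alt_base, zygosity, allele, is_ti)
            )
    return records


def write_snv_log(records: Iterable[SNVRecord], path) -> None:
    """TSV truth log: chrom, pos (1-based), ref, alt, zygosity, allele, ti_or_tv."""
    with open(path, "w") as out:
        out.write("chrom\tpos\tref\talt\tzygosity\tallele\tti_or_tv\n")
        for r in records:
            out.write(
                f"{r.chrom}\t{r.pos}\t{r.ref_base}\t{r.alt_base}\t{r.zygosity}\t"
                f"{r.allele}\t{'ti' if r.is_transition else 'tv'}\n"
            )


def read_snv_log(path) -> list[SNVRecord]:
    records: list[SNVRecord] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: not an SNV truth log")
        for line in handle:
            chrom, pos, ref, alt, zyg, allele, titv = line.rstrip("\n").split("\t")
            records.append(
                SNVRecord(
                    chrom,
                    int(pos),
                    ref,
                    alt,
                    zyg,
                    allele if allele == "both" else int(allele),
                    titv == "ti",
                )
            )
    return records


def write_snv_vcf(records: Iterable[SNVRecord], path, contigs: dict[str, int]) -> None:
    """Minimal VCF 4.2 rendering of the SNV truth set (GT 0/1 or 1/1)."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            out.write(f"##contig=<ID={name},length={length}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsimulated\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            gt = "1/1" if r.zygosity == "hom" else "0/1"
            out.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_base}\t{r.alt_base}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def titv_ratio(records: Sequence[SNVRecord]) -> float:
    """Observed transitions / transversions of a simulated set."""
    ti = sum(1 for r in records if r.is_transition)
    tv = len(records) - ti
    if tv == 0:
        raise ZeroDivisionError("no transversions in the set")
    return ti / tv
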