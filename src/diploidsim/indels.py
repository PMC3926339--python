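"""Insertion/deletion simulation with over-generation and duplicate removal.

Candidates are drawn uniformly over the sequenced (non-N) genome, 5% more
than requested to cover the losses at the duplicate-removal step. Each
candidate belongs to one of four categories — 30% single-base, 20% repeat
expansions, 49% mid-size (2-20 bp), 1% long (21-100 bp) — apportioned by
largest remainder so the counts are exact. Insertions and deletions are
balanced 1:1, as are heterozygous and homozygous indels; heterozygous
records go to allele 1 or 2 by fair coin and the truth set is emitted as
two allele-specific logs.

Repeat expansions are realized as tandem-motif insertions: the motif (1-5
bp) immediately left of the anchor is inserted again as 2-4 extra copies.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .reference import ReferenceGenome

CATEGORIES = ("single", "repeat_expansion", "mid", "long")
BASES = "ACGT"


@dataclass
class IndelConfig:
    n_indels: int | None = None
    indel_rate: float | None = None  # alternative to n_indels: per-base rate
    overgen_fraction: float = 0.05
    frac_single_base: float = 0.30
    frac_repeat_expansion: float = 0.20
    frac_2_20: float = 0.49
    frac_long: float = 0.01
    ins_fraction: float = 0.5  # insertion:deletion = 1:1
    het_fraction: float = 0.5  # het:hom = 1:1
    mid_size_range: tuple[int, int] = (2, 20)
    long_size_range: tuple[int, int] = (21, 100)
    motif_size_range: tuple[int, int] = (1, 5)
    motif_copy_range: tuple[int, int] = (2, 4)
    max_redraws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        total = (
            self.frac_single_base
            + self.frac_repeat_expansion
            + self.frac_2_20
            + self.frac_long
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if self.n_indels is None and self.indel_rate is None:
            raise ValueError("one of n_indels or indel_rate is required")

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (
            self.frac_single_base,
            self.frac_repeat_expansion,
            self.frac_2_20,
            self.frac_long,
        )

    def resolve_count(self, genome_length: int) -> int:
        if self.n_indels is not None:
            return int(self.n_indels)
        return int(round(self.indel_rate * genome_length))


@dataclass
class IndelRecord:
    chrom: str
    pos: int  # 1-based; insertion: anchor base, deletion: first deleted base
    kind: str  # "insertion" | "deletion"
    length: int
    seq: str  # inserted or deleted bases
    category: str
    zygosity: str = "hom"
    allele: int | str = "both"

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive reference span occupied by this indel."""
        if self.kind == "deletion":
            return (self.pos, self.pos + self.length - 1)
        return (self.pos, self.pos)

    @property
    def length_delta(self) -> int:
        return self.length if self.kind == "insertion" else -self.length

    @property
    def size_class(self) -> str:
        """Short/medium/large tripartition (1-10 / 11-20 / 21-100 bp)."""
        if self.length <= 10:
            return "short"
        if self.length <= 20:
            return "medium"
        return "large"


def overgenerate_count(n_requested: int, overgen_fraction: float = 0.05) -> int:
    """Initial candidate count: requested plus the over-generation margin."""
    if n_requested < 0:
        raise ValueError("n_requested must be >= 0")
    return math.ceil(n_requested * (1.0 + overgen_fraction))


def allocate_categories(
    n: int, fractions: Sequence[float] = (0.30, 0.20, 0.49, 0.01)
) -> tuple[int, ...]:
    """Largest-remainder apportionment of n across the category fractions."""
    quotas = [n * f for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    shortfall = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:shortfall]:
        counts[i] += 1
    return tuple(counts)


def _in_n_region(z: int, regions: Sequence[tuple[int, int]], starts: Sequence[int]) -> bool:
    i = bisect_right(starts, z) - 1
    return i >= 0 and z < regions[i][1]


def _span_touches_n(
    z0: int, z1: int, regions: Sequence[tuple[int, int]], starts: Sequence[int]
) -> bool:
    """Whether [z0, z1) (0-based) intersects any N interval."""
    i = bisect_right(starts, z0) - 1
    if i >= 0 and z0 < regions[i][1]:
        return True
    j = bisect_right(starts, z1 - 1) - 1
    return j > i


def sample_indel(
    genome: ReferenceGenome,
    category: str,
    cfg: IndelConfig,
    rng: np.random.Generator,
) -> IndelRecord:
    """Draw one indel candidate of the given category, avoiding N-regions.

    Positions are redrawn (up to ``cfg.max_redraws``) while the anchor, the
    deletion span, or the repeat-expansion motif context touches an N-region
    or runs off the chromosome.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    names = list(genome.chromosomes)
    lengths = np.array([genome.chrom_length(c) for c in names], dtype=float)
    weights = lengths / lengths.sum()

    for _ in range(cfg.max_redraws):
        chrom = names[int(rng.choice(len(names), p=weights))]
        sequence = genome.chromosomes[chrom]
        chrom_len = len(sequence)
        regions = genome.n_regions.get(chrom, [])
        starts = [iv[0] for iv in regions]

        if category == "repeat_expansion":
            motif_len = int(rng.integers(cfg.motif_size_range[0], cfg.motif_size_range[1] + 1))
            copies = int(rng.integers(cfg.motif_copy_range[0], cfg.motif_copy_range[1] + 1))
            pos = int(rng.integers(motif_len, chrom_len)) + 1  # need motif_len left context
            z = pos - 1
            if _span_touches_n(z - motif_len + 1, z + 1, regions, starts):
                continue
            motif = sequence[z - motif_len + 1 : z + 1]
            seq = motif * copies
            return IndelRecord(chrom, pos, "insertion", len(seq), seq, category)

        if category == "single":
            length = 1
        elif category == "mid":
            length = int(rng.integers(cfg.mid_size_range[0], cfg.mid_size_range[1] + 1))
        else:
            length = int(rng.integers(cfg.long_size_range[0], cfg.long_size_range[1] + 1))

        # repeat expansions are structurally insertions, so the coin for the
        # remaining categories is compensated to keep the OVERALL insertion
        # fraction at cfg.ins_fraction (1:1 by default)
        f_rep = cfg.frac_repeat_expansion
        p_ins = min(max((cfg.ins_fraction - f_rep) / max(1.0 - f_rep, 1e-12), 0.0), 1.0)
        is_insertion = rng.random() < p_ins
        if is_insertion:
            pos = int(rng.integers(1, chrom_len + 1))
            if _in_n_region(pos - 1, regions, starts):
                continue
            seq = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
            return IndelRecord(chrom, pos, "insertion", length, seq, category)
        if chrom_len < length:
            continue
        pos = int(rng.integers(1, chrom_len - length + 2))
        if _span_touches_n(pos - 1, pos - 1 + length, regions, starts):
            continue
        seq = sequence[pos - 1 : pos - 1 + length]
        return IndelRecord(chrom, pos, "deletion", length, seq, category)

    raise RuntimeError(
        f"could not place a {category} indel after {cfg.max_redraws} redraws "
        "(chromosomes may be effectively all-N)"
    )


def dedup_sort(candidates: Sequence[IndelRecord], n_requested: int | None = None) -> list[IndelRecord]:
    """Coordinate-sort, keep the first record per (chrom, pos), drop span
    overlaps with previously kept records, and trim the excess from the tail."""
    kept: list[IndelRecord] = []
    last_end: dict[str, int] = {}
    seen: set[tuple[str, int]] = set()
    for rec in sorted(candidates, key=lambda r: (r.chrom, r.pos)):
        key = (rec.chrom, rec.pos)
        if key in seen:
            continue
        s, e = rec.span
        if rec.chrom in last_end and s <= last_end[rec.chrom]:
            continue
        seen.add(key)
        last_end[rec.chrom] = e
        kept.append(rec)
    if n_requested is not None:
        kept = kept[:n_requested]
    return kept


def assign_indel_zygosity(
    records: Iterable[IndelRecord], het_fraction: float, rng: np.random.Generator
) -> list[IndelRecord]:
    """Assign het/hom and the carrying allele in place; returns the list."""
    out = list(records)
    for rec in out:
        if rng.random() < het_fraction:
            rec.zygosity = "het"
            rec.allele = 1 + int(rng.integers(2))
        else:
            rec.zygosity = "hom"
            rec.allele = "both"
    return out


def simulate_indels(
    genome: ReferenceGenome,
    cfg: IndelConfig,
    rng: np.random.Generator | None = None,
) -> list[IndelRecord]:
    """End-to-end indel simulation: over-generate, allocate, place, dedup, assign."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_requested = cfg.resolve_count(genome.total_length)
    n_initial = overgenerate_count(n_requested, cfg.overgen_fraction)
    counts = allocate_categories(n_initial, cfg.fractions)
    candidates: list[IndelRecord] = []
    for category, count in zip(CATEGORIES, counts):
        for _ in range(count):
            candidates.append(sample_indel(genome, category, cfg, rng))
    records = dedup_sort(candidates, n_requested)
    return assign_indel_zygosity(records, cfg.het_fraction, rng)


def allele_records(records: Iterable[IndelRecord], allele_index: int) -> list[IndelRecord]:
    return [r for r in records if r.allele == "both" or r.allele == allele_index]


def write_indel_logs(records: Sequence[IndelRecord], path_allele1, path_allele2) -> None:
    """Two allele-specific TSV truth logs (bi-allelic model)."""
    for path, allele_index in ((path_allele1, 1), (path_allele2, 2)):
        with open(path, "w") as out:
            out.write("chrom\tpos\tkind\tlength\tseq\tcategory\tzygosity\n")
            for r in allele_records(records, allele_index):
                out.write(
                    f"{r.chrom}\t{r.pos}\t{r.kind}\t{r.length}\t{r.seq}\t"
                    f"{r.category}\t{r.zygosity}\n"
                )


def read_indel_log(path, allele_index: int) -> list[IndelRecord]:
    records: list[IndelRecord] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: not an indel truth log")
        for line in handle:
            chrom, pos, kind, length, seq, category, zyg = line.rstrip("\n").split("\t")
            allele = "both" if zyg == "hom" else allele_index
            records.append(
                IndelRecord(chrom, int(pos), kind, int(length), seq, category, zyg, allele)
            )
    return records


def write_indel_vcf(
    records: Sequence[IndelRecord], path, genome: ReferenceGenome
) -> None:
    """VCF 4.2 rendering with left-anchored REF/ALT alleles."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for name, seq in genome.chromosomes.items():
            out.write(f"##contig=<ID={name},length={len(seq)}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsimulated\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            sequence = genome.chromosomes[r.chrom]
            if r.kind == "insertion":
                anchor = sequence[r.pos - 1]
                ref, alt, pos = anchor, anchor + r.seq, r.pos
            else:
                anchor = sequence[r.pos - 2] if r.pos > 1 else sequence[r.pos - 1 + r.length]
                if r.pos > 1:
                    ref, alt, pos = anchor + r.seq, anchor, r.pos - 1
                else:  # deletion at chromosome start anchors on the following base
                    ref, alt, pos = r.seq + anchor, anchor, r.pos
            gt = "1/1" if r.zygosity == "hom" else "0/1"
            out.write(f"{r.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")
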