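"""Allele-specific copy-number-variant simulation.

CNV size and location are generated dynamically by rejection sampling:
each candidate gets a uniform size within the user's bounds and a uniform
start on a length-weighted chromosome; it is accepted only if the span
respects the chromosomal boundary on both alleles (accounting for the net
length shift the simulated indels impose per allele), does not overlap an
already accepted CNV, and neither boundary falls inside a simulated indel
on either allele. Gains are realized downstream as tandem duplications
(copy number 2..max adjacent copies), losses as full-span deletions; copy
number is stored per allele, 1 meaning unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .indels import IndelRecord
from .reference import ReferenceGenome


@dataclass
class CNVConfig:
    n_cnvs: int = 0
    size_min: int = 1000
    size_max: int = 10000
    gain_fraction: float = 0.5
    max_copy_number: int = 4
    allele_mode: str = "random"  # "one" | "both" | "random"
    retry_factor: int = 1000  # retry budget = retry_factor * n_cnvs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.size_min <= self.size_max:
            raise ValueError("need 1 <= size_min <= size_max")
        if self.max_copy_number < 2:
            raise ValueError("max_copy_number must be >= 2")
        if self.allele_mode not in ("one", "both", "random"):
            raise ValueError("allele_mode must be one|both|random")


@dataclass
class CNVRecord:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    copy_number_allele1: int  # 1 = unchanged, 0 = loss, >=2 = tandem gain
    copy_number_allele2: int

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "CNVRecord") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


class CNVPlacementError(RuntimeError):
    """Raised when the retry budget is exhausted before all CNVs are placed."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed} of {requested} CNVs before exhausting the "
            "retry budget; relax sizes/counts or raise retry_factor"
        )


def sample_cnv_candidate(
    genome: ReferenceGenome, cfg: CNVConfig, rng: np.random.Generator
) -> CNVRecord:
    """One dynamic size/location candidate; validity is checked separately."""
    names = list(genome.chromosomes)
    lengths = np.array([genome.chrom_length(c) for c in names], dtype=float)
    chrom = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
    chrom_len = genome.chrom_length(chrom)
    size = int(rng.integers(cfg.size_min, cfg.size_max + 1))
    size = min(size, chrom_len)
    start = int(rng.integers(1, chrom_len - size + 2))
    is_gain = rng.random() < cfg.gain_fraction
    cn = int(rng.integers(2, cfg.max_copy_number + 1)) if is_gain else 0

    if cfg.allele_mode == "both":
        affected = (True, True)
    elif cfg.allele_mode == "one":
        affected = (True, False) if rng.random() < 0.5 else (False, True)
    else:  # random: fair coin per allele, at least one affected
        affected = (rng.random() < 0.5, rng.random() < 0.5)
        if not any(affected):
            affected = (True, False) if rng.random() < 0.5 else (False, True)
    cn1 = cn if affected[0] else 1
    cn2 = cn if affected[1] else 1
    return CNVRecord(chrom, start, start + size - 1, cn1, cn2)


def _boundary_in_indel(boundary: int, spans: Sequence[tuple[int, int]]) -> bool:
    return any(s <= boundary <= e for s, e in spans)


def validate_cnv(
    candidate: CNVRecord,
    chrom_length: int,
    accepted: Sequence[CNVRecord],
    indels_allele1: Sequence[IndelRecord],
    indels_allele2: Sequence[IndelRecord],
) -> bool:
    """Boundary, CNV-overlap and indel-collision checks for one candidate.

    The chromosome-boundary check is allele-aware: on an allele whose
    simulated indels shorten the chromosome, the usable span shrinks by the
    net length deficit.
    """
    per_allele = (indels_allele1, indels_allele2)
    for indels in per_allele:
        delta = sum(
            r.length_delta for r in indels if r.chrom == candidate.chrom
        )
        if candidate.start < 1 or candidate.end > chrom_length + min(0, delta):
            return False
    for other in accepted:
        if candidate.overlaps(other):
            return False
    for indels in per_allele:
        spans = [r.span for r in indels if r.chrom == candidate.chrom]
        if _boundary_in_indel(candidate.start, spans):
            return False
        if _boundary_in_indel(candidate.end, spans):
            return False
    return True


def simulate_cnvs(
    genome: ReferenceGenome,
    cfg: CNVConfig,
    indels: Sequence[IndelRecord] = (),
    rng: np.random.Generator | None = None,
) -> list[CNVRecord]:
    """Rejection-sample CNVs until ``cfg.n_cnvs`` are accepted.

    Raises :class:`CNVPlacementError` if the retry budget
    (``retry_factor * n_cnvs`` candidates) runs out first.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    indels_a1 = [r for r in indels if r.allele in ("both", 1)]
    indels_a2 = [r for r in indels if r.allele in ("both", 2)]
    accepted: list[CNVRecord] = []
    budget = cfg.retry_factor * cfg.n_cnvs
    tries = 0
    while len(accepted) < cfg.n_cnvs:
        if tries >= budget:
            raise CNVPlacementError(len(accepted), cfg.n_cnvs)
        tries += 1
        cand = sample_cnv_candidate(genome, cfg, rng)
        if cand.size < cfg.size_min:  # chromosome shorter than size_min
            continue
        if validate_cnv(
            cand, genome.chrom_length(cand.chrom), accepted, indels_a1, indels_a2
        ):
            accepted.append(cand)
    accepted.sort(key=lambda r: (r.chrom, r.start))
    return accepted


def write_cnv_table(records: Sequence[CNVRecord], path) -> None:
    """Tabular truth file with both alleles' copy numbers (1-based inclusive)."""
    with open(path, "w") as out:
        out.write("chrom\tstart\tend\tsize\tcn_allele1\tcn_allele2\n")
        for r in records:
            out.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.size}\t"
                f"{r.copy_number_allele1}\t{r.copy_number_allele2}\n"
            )


def write_cnv_bed(records: Sequence[CNVRecord], path) -> None:
    """Simplified BED-like rendering (0-based half-open) for genome browsers."""
    with open(path, "w") as out:
        for k, r in enumerate(records, start=1):
            score = max(r.copy_number_allele1, r.copy_number_allele2)
            out.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tcnv_{k}\t{score}\n")


def read_cnv_table(path) -> list[CNVRecord]:
    records: list[CNVRecord] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: not a CNV table")
        for line in handle:
            chrom, start, end, _size, cn1, cn2 = line.rstrip("\n").split("\t")
            records.append(CNVRecord(chrom, int(start), int(end), int(cn1), int(cn2)))
    return records
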