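"""Truth-set rediscovery evaluation.

Compares a variant caller's VCF against the simulator's truth logs and
reports the percentage of truth variants rediscovered, stratified by
variant type, zygosity, and indel size bin (1-6, 7-10, 11-20, 21-100 bp).
The callers themselves are external; only the comparison lives here.

Matching rules (declared, since no community standard exists): SNVs must
match chrom, position and alternate base exactly; indels must match chrom,
kind and length, with the position allowed to differ by a configurable
tolerance (default 10 bases) to absorb left/right-alignment ambiguity.
Each truth record is matched to at most one call, greedily by nearest
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pysam

from .indels import IndelRecord
from .snv import SNVRecord

INDEL_SIZE_BINS = ((1, 6), (7, 10), (11, 20), (21, 100))


@dataclass
class CalledVariant:
    chrom: str
    pos: int  # 1-based; indels use the same anchoring as truth records
    kind: str  # "snv" | "insertion" | "deletion"
    alt: str
    length: int


@dataclass
class Stratum:
    truth: int = 0
    matched: int = 0

    @property
    def percent(self) -> float:
        return 100.0 * self.matched / self.truth if self.truth else 0.0


@dataclass
class RediscoveryReport:
    position_tolerance: int
    strata: dict[str, Stratum] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Stratum:
        return self.strata[name]

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("stratum\ttruth\tmatched\tpercent\n")
            for name, s in self.strata.items():
                out.write(f"{name}\t{s.truth}\t{s.matched}\t{s.percent:.2f}\n")

    def __str__(self) -> str:
        lines = [f"rediscovery report (indel position tolerance {self.position_tolerance} bp)"]
        for name, s in self.strata.items():
            lines.append(f"  {name:<16} {s.matched:>8}/{s.truth:<8} {s.percent:6.2f}%")
        return "\n".join(lines)


def read_called_vcf(path) -> list[CalledVariant]:
    """Parse a VCF 4.x into normalized called variants.

    Insertions/deletions are converted from left-anchored REF/ALT to the
    truth-log anchoring (insertion after the anchor base; deletion position
    is the first deleted base).
    """
    calls: list[CalledVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if alt is None or alt.startswith("<"):
                    continue
                ref = rec.ref
                if len(ref) == 1 and len(alt) == 1:
                    calls.append(CalledVariant(rec.chrom, rec.pos, "snv", alt, 1))
                elif len(alt) > len(ref) and alt.startswith(ref):
                    ins = alt[len(ref):]
                    calls.append(
                        CalledVariant(rec.chrom, rec.pos + len(ref) - 1, "insertion", ins, len(ins))
                    )
                elif len(ref) > len(alt) and ref.startswith(alt):
                    removed = ref[len(alt):]
                    calls.append(
                        CalledVariant(
                            rec.chrom, rec.pos + len(alt), "deletion", removed, len(removed)
                        )
                    )
                # complex substitutions fall outside the simulated truth space
    return calls


def _check_chrom_names(truth_chroms: set[str], called: Sequence[CalledVariant]) -> None:
    called_chroms = {c.chrom for c in called}
    unmatched = called_chroms - truth_chroms
    if called_chroms and truth_chroms and not (called_chroms & truth_chroms):
        raise ValueError(
            "no chromosome names shared between truth and calls; "
            f"unmatched call chromosomes: {sorted(unmatched)}"
        )


def match_variants(
    truth_snvs: Sequence[SNVRecord],
    truth_indels: Sequence[IndelRecord],
    called: Sequence[CalledVariant],
    position_tolerance: int = 10,
) -> RediscoveryReport:
    """Match truth variants to calls and tabulate per-stratum rediscovery."""
    truth_chroms = {r.chrom for r in truth_snvs} | {r.chrom for r in truth_indels}
    _check_chrom_names(truth_chroms, called)

    report = RediscoveryReport(position_tolerance)
    strata = report.strata
    for name in ("snv", "snv_het", "snv_hom", "indel"):
        strata[name] = Stratum()
    for lo, hi in INDEL_SIZE_BINS:
        strata[f"indel_{lo}_{hi}"] = Stratum()

    snv_calls = {(c.chrom, c.pos, c.alt) for c in called if c.kind == "snv"}
    for rec in truth_snvs:
        strata["snv"].truth += 1
        zyg = strata["snv_het"] if rec.zygosity == "het" else strata["snv_hom"]
        zyg.truth += 1
        if (rec.chrom, rec.pos, rec.alt_base) in snv_calls:
            strata["snv"].matched += 1
            zyg.matched += 1

    # indels: greedy nearest-position matching within tolerance, per (chrom, kind, length)
    pools: dict[tuple[str, str, int], list[int]] = {}
    for c in called:
        if c.kind in ("insertion", "deletion"):
            pools.setdefault((c.chrom, c.kind, c.length), []).append(c.pos)
    for positions in pools.values():
        positions.sort()

    def bin_name(length: int) -> str | None:
        for lo, hi in INDEL_SIZE_BINS:
            if lo <= length <= hi:
                return f"indel_{lo}_{hi}"
        return None

    for rec in sorted(truth_indels, key=lambda r: (r.chrom, r.pos)):
        strata["indel"].truth += 1
        bname = bin_name(rec.length)
        if bname:
            strata[bname].truth += 1
        pool = pools.get((rec.chrom, rec.kind, rec.length))
        if not pool:
            continue
        # nearest unmatched call position
        best_i = min(range(len(pool)), key=lambda i: abs(pool[i] - rec.pos))
        if abs(pool[best_i] - rec.pos) <= position_tolerance:
            pool.pop(best_i)
            strata["indel"].matched += 1
            if bname:
                strata[bname].matched += 1
    return report


def evaluate_vcf(
    truth_snvs: Sequence[SNVRecord],
    truth_indels: Sequence[IndelRecord],
    vcf_path,
    position_tolerance: int = 10,
) -> RediscoveryReport:
    """Convenience wrapper: parse the VCF then run :func:`match_variants`."""
    return match_variants(
        truth_snvs, truth_indels, read_called_vcf(vcf_path), position_tolerance
    )
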