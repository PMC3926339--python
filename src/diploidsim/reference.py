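"""Reference genome I/O and diploid allele realization.

A :class:`ReferenceGenome` holds uppercase chromosome sequences plus the
intervals of undetermined bases (N-regions).  Variant truth sets (SNVs,
indels, CNVs) are turned into concrete per-allele nucleotide sequences by
:func:`apply_variants`, which also builds a monotone reference→allele
coordinate map so that downstream consumers (read provenance, depth
checks) can translate coordinates across indel/CNV shifts.

Conventions: internal coordinates are 0-based half-open; every public
truth record uses 1-based coordinates (inclusive spans), matching
VCF-style output. Insertions anchor AFTER their stated reference base.
"""

from __future__ import annotations

import gzip
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TYPE_CHECKING

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints
    from .snv import SNVRecord
    from .indels import IndelRecord
    from .cnv import CNVRecord

_NON_ACGT = re.compile(r"[^ACGT]+")
_VALID = re.compile(r"^[A-Za-z*\-]*$")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty records, duplicate names)."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and collapse every non-ACGT code to N.

    IUPAC ambiguity codes (R, Y, S, W, ...) carry no usable base identity
    for variant placement, so they are treated the same as N.
    """
    seq = seq.upper()
    return _NON_ACGT.sub(lambda m: "N" * len(m.group()), seq)


def find_n_regions(sequence: str) -> list[tuple[int, int]]:
    """Maximal runs of non-ACGT characters as sorted disjoint [start, end) intervals."""
    return [(m.start(), m.end()) for m in _NON_ACGT.finditer(sequence)]


@dataclass
class ReferenceGenome:
    """Named chromosome sequences with precomputed N-region intervals."""

    chromosomes: dict[str, str]
    n_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.n_regions:
            self.n_regions = {
                name: find_n_regions(seq) for name, seq in self.chromosomes.items()
            }

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def chrom_length(self, name: str) -> int:
        return len(self.chromosomes[name])

    @classmethod
    def from_sequences(cls, chromosomes: dict[str, str]) -> "ReferenceGenome":
        return cls({name: normalize_sequence(seq) for name, seq in chromosomes.items()})


def read_fasta(path) -> ReferenceGenome:
    """Parse a (possibly gzipped) FASTA file into a :class:`ReferenceGenome`.

    Sequences are normalized (uppercase; non-ACGT → N) and N-regions are
    computed. Chromosome order follows file order.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    chromosomes: dict[str, str] = {}
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if not name:
                raise FastaParseError(f"{path}: record with empty header")
            if name in chromosomes:
                raise FastaParseError(f"{path}: duplicate chromosome name {name!r}")
            seq = str(record.seq)
            if not seq:
                raise FastaParseError(f"{path}: record {name!r} has empty sequence")
            chromosomes[name] = normalize_sequence(seq)
    if not chromosomes:
        raise FastaParseError(f"{path}: no FASTA records found")
    return ReferenceGenome(chromosomes)


class CoordMap:
    """Monotone map from reference positions to allele positions (0-based).

    Built from the replacement edits applied to one chromosome. Positions
    inside a deleted (or shortened) segment map to the segment's left edge
    on the allele.
    """

    def __init__(self, edits: Sequence[tuple[int, int, int]], ref_length: int):
        # edits: (ref_start, ref_end, replacement_length), sorted, disjoint
        self._starts: list[int] = []
        self._ends: list[int] = []
        self._allele_starts: list[int] = []
        self._repl_lens: list[int] = []
        shift = 0
        for a, b, m in edits:
            self._starts.append(a)
            self._ends.append(b)
            self._allele_starts.append(a + shift)
            self._repl_lens.append(m)
            shift += m - (b - a)
        self._ref_length = ref_length
        self._total_shift = shift

    @property
    def allele_length_delta(self) -> int:
        return self._total_shift

    def __call__(self, ref_pos: int) -> int:
        """Allele position (0-based) for a 0-based reference position."""
        if not 0 <= ref_pos <= self._ref_length:
            raise IndexError(f"reference position {ref_pos} out of range")
        i = bisect_right(self._starts, ref_pos) - 1
        if i < 0:
            return ref_pos
        a, b = self._starts[i], self._ends[i]
        allele_a, m = self._allele_starts[i], self._repl_lens[i]
        if ref_pos >= b:
            return ref_pos + (allele_a - a) + (m - (b - a))
        # inside the edited span: clamp into the replacement (left edge for deletions)
        return allele_a + min(ref_pos - a, max(m - 1, 0))


@dataclass
class AlleleSequence:
    """One chromosome's sequence after variant application, with its coordinate map."""

    chrom: str
    allele_index: int
    sequence: str
    coord_map: CoordMap

    @property
    def name(self) -> str:
        return f"{self.chrom}_allele{self.allele_index}"


def _variant_applies(zygosity: str, allele: int | str, allele_index: int) -> bool:
    if zygosity == "hom":
        return True
    return int(allele) == allele_index


def _point_edit(rec, kind_hint: str) -> tuple[int, int, str]:
    """Translate an SNV or indel record into a (start, end, replacement) edit."""
    if kind_hint == "snv":
        return (rec.pos - 1, rec.pos, rec.alt_base)
    if rec.kind == "insertion":
        return (rec.pos, rec.pos, rec.seq)  # after the anchor base
    return (rec.pos - 1, rec.pos - 1 + rec.length, "")  # deletion


def _apply_edits(sequence: str, edits: list[tuple[int, int, str]]) -> str:
    parts: list[str] = []
    cursor = 0
    for a, b, repl in edits:
        parts.append(sequence[cursor:a])
        parts.append(repl)
        cursor = b
    parts.append(sequence[cursor:])
    return "".join(parts)


def apply_variants(
    reference: ReferenceGenome,
    snvs: Iterable["SNVRecord"] = (),
    indels: Iterable["IndelRecord"] = (),
    cnvs: Iterable["CNVRecord"] = (),
    allele_index: int = 1,
) -> dict[str, AlleleSequence]:
    """Realize one allele of the diploid genome from the variant truth sets.

    Homozygous variants apply to both alleles; heterozygous variants only to
    the allele they were assigned. CNV gains become tandem copies of the
    (point-variant-mutated) span; CNV losses remove it. Point variants
    strictly inside a CNV span are applied within the copied segment; an SNV
    falling inside a deletion span is a no-op on that allele (the base is
    gone). Overlaps between point variants of the same class raise, since
    upstream simulation guarantees disjoint placements.
    """
    if allele_index not in (1, 2):
        raise ValueError("allele_index must be 1 or 2")

    by_chrom_points: dict[str, list[tuple[int, int, str]]] = {}
    for rec in snvs:
        if _variant_applies(rec.zygosity, rec.allele, allele_index):
            by_chrom_points.setdefault(rec.chrom, []).append(_point_edit(rec, "snv"))
    for rec in indels:
        if _variant_applies(rec.zygosity, rec.allele, allele_index):
            by_chrom_points.setdefault(rec.chrom, []).append(_point_edit(rec, "indel"))

    by_chrom_cnvs: dict[str, list] = {}
    for rec in cnvs:
        cn = rec.copy_number_allele1 if allele_index == 1 else rec.copy_number_allele2
        if cn != 1:
            by_chrom_cnvs.setdefault(rec.chrom, []).append((rec.start - 1, rec.end, cn))

    out: dict[str, AlleleSequence] = {}
    for chrom, sequence in reference.chromosomes.items():
        L = len(sequence)
        points = sorted(by_chrom_points.get(chrom, []))
        cnv_edits = sorted(by_chrom_cnvs.get(chrom, []))
        for a, b, repl in points:
            if not (0 <= a <= b <= L):
                raise ValueError(f"variant at {chrom}:{a + 1} outside chromosome")
        for a, b, _ in cnv_edits:
            if not (0 <= a < b <= L):
                raise ValueError(f"CNV span {chrom}:{a + 1}-{b} outside chromosome")

        # fold point edits nested inside CNV spans into the CNV replacement
        edits: list[tuple[int, int, str]] = []
        consumed = [False] * len(points)
        for a, b, cn in cnv_edits:
            nested: list[tuple[int, int, str]] = []
            for i, (pa, pb, repl) in enumerate(points):
                if pa >= a and pb <= b and not (pa == pb == a) and not (pa == pb == b):
                    nested.append((pa - a, pb - a, repl))
                    consumed[i] = True
            segment = _apply_edits(sequence[a:b], nested)
            edits.append((a, b, segment * cn))
        for i, (pa, pb, repl) in enumerate(points):
            if not consumed[i]:
                edits.append((pa, pb, repl))
        edits.sort(key=lambda e: (e[0], e[1]))

        # SNV-inside-deletion concession: substituting a base that a deletion
        # removes on this allele is a no-op, so such SNVs are dropped first
        del_starts = [a for a, b, repl in edits if repl == "" and b > a]
        del_ends = [b for a, b, repl in edits if repl == "" and b > a]

        def _in_deletion(pos: int) -> bool:
            i = bisect_right(del_starts, pos) - 1
            return i >= 0 and pos < del_ends[i]

        edits = [
            (a, b, repl)
            for a, b, repl in edits
            if not (b - a == 1 and len(repl) == 1 and _in_deletion(a))
        ]

        cleaned: list[tuple[int, int, str]] = []
        for a, b, repl in edits:
            if cleaned and a < cleaned[-1][1]:
                pa, pb, _ = cleaned[-1]
                raise ValueError(
                    f"overlapping variants on {chrom} allele {allele_index}: "
                    f"[{pa},{pb}) and [{a},{b})"
                )
            if cleaned and a == cleaned[-1][0] == cleaned[-1][1] == b:
                raise ValueError(f"colliding insertions at {chrom}:{a}")
            cleaned.append((a, b, repl))

        mutated = _apply_edits(sequence, cleaned)
        cmap = CoordMap([(a, b, len(r)) for a, b, r in cleaned], L)
        out[chrom] = AlleleSequence(chrom, allele_index, mutated, cmap)
    return out


def write_fasta(sequences: Iterable[AlleleSequence], path, width: int = 70) -> None:
    """Write allele sequences as wrapped FASTA with ``<chrom>_allele<k>`` headers."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as out:
        for allele in sequences:
            out.write(f">{allele.name}\n")
            seq = allele.sequence
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
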