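"""Short-read generation from realized allele sequences.

Reads are drawn fragment-by-fragment from the two mutated allele sequences
(length-proportionally across chromosomes and alleles), so heterozygous
variant allele fractions and CNV depth signals emerge naturally. Paired
fragments have length 2*read_length + inner_distance where the inner
distance — the gap BETWEEN the mates, not the fragment length — is
Normal(insert_mean, insert_sd) rounded and floored at 0. Mate 1 is the
first read_length bases of the fragment and mate 2 the reverse complement
of the last read_length bases; by default a fair coin swaps which physical
strand mate 1 comes from, so variant strands stay balanced.

Base qualities come from an empirical :class:`~diploidsim.quality.QualityProfile`
and drive substitution errors at the Phred rate 10^(-q/10) per cycle.

Parallel contract: the workload is always partitioned into a fixed number
of chunks (four, matching the quad-core target of the original design),
each owning an independent seed-derived random stream, and chunk outputs
are concatenated in order — so the FASTQ bytes are identical whether the
chunks are executed by 1 worker or 4.
"""

from __future__ import annotations

import gzip
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .quality import QualityProfile, phred_error_prob
from .reference import AlleleSequence

N_CHUNKS = 4  # fixed partition; cfg.workers only controls concurrency

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadGenConfig:
    coverage: float = 15.0
    read_length: int = 100
    paired: bool = True
    insert_mean: float = 200.0  # inner distance between mates, bases
    insert_sd: float = 20.0
    workers: int = 1
    strand_flip: bool = True
    seed: int = 0
    max_fragment_retries: int = 100

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.insert_mean < 0:
            raise ValueError("insert_mean must be >= 0")
        if not 1 <= self.workers <= 4:
            raise ValueError("workers must be between 1 and 4")


@dataclass
class ReadPair:
    name: str
    seq1: str
    qual1: str
    seq2: str | None = None
    qual2: str | None = None


def compute_pair_count(
    coverage: float, total_allele_length: int, read_length: int, paired: bool
) -> int:
    """Number of pairs (or single reads) needed for the requested fold coverage.

    ``total_allele_length`` sums BOTH allele sequences; coverage is measured
    against that diploid length, so emitted bases = coverage * total length.
    """
    reads_factor = 2 if paired else 1
    return int(round(coverage * total_allele_length / (reads_factor * read_length)))


def make_read_name(chrom: str, allele: int, start: int, end: int, index: int) -> str:
    """Provenance-encoding read name: 1-based inclusive fragment span on the allele."""
    return f"sim|{chrom}|a{allele}|{start}|{end}|{index}"


def decode_read_name(name: str) -> tuple[str, int, int, int, int]:
    """Invert :func:`make_read_name` → (chrom, allele, start, end, index)."""
    name = name.split("/")[0]
    tag, chrom, allele, start, end, index = name.split("|")
    if tag != "sim":
        raise ValueError(f"not a simulated read name: {name!r}")
    return chrom, int(allele[1:]), int(start), int(end), int(index)


def draw_fragment(
    allele_length: int, cfg: ReadGenConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """One fragment as (0-based start, length); redraws if it cannot fit."""
    for _ in range(cfg.max_fragment_retries):
        if cfg.paired:
            d = max(0, int(round(rng.normal(cfg.insert_mean, cfg.insert_sd))))
            frag_len = 2 * cfg.read_length + d
        else:
            frag_len = cfg.read_length
        if frag_len > allele_length:
            continue
        start = int(rng.integers(0, allele_length - frag_len + 1))
        return start, frag_len
    raise RuntimeError(
        f"no fragment of the configured geometry fits an allele of length "
        f"{allele_length} after {cfg.max_fragment_retries} draws"
    )


def inject_errors(seq: str, quals: np.ndarray, rng: np.random.Generator) -> str:
    """Substitution errors per cycle at probability 10^(-q/10); N never mutated."""
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    p = phred_error_prob(quals)
    hit = (rng.random(len(seq)) < p) & (codes >= 0)
    shift = rng.integers(1, 4, size=len(seq))
    out = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out[hit] = _CODE_BASE[(codes[hit] + shift[hit]) % 4]
    return out.tobytes().decode()


def make_read_pair(
    allele: AlleleSequence,
    fragment: tuple[int, int],
    profile: QualityProfile,
    rng: np.random.Generator,
    index: int = 0,
    strand_flip: bool = False,
) -> ReadPair:
    """Extract one pair from a fragment, sample qualities, inject errors."""
    start, frag_len = fragment
    L = profile.read_length
    frag = allele.sequence[start : start + frag_len]
    fwd = frag[:L]
    rev = reverse_complement(frag[-L:])
    flipped = strand_flip and rng.random() < 0.5
    seq1, seq2 = (rev, fwd) if flipped else (fwd, rev)
    name = make_read_name(allele.chrom, allele.allele_index, start + 1, start + frag_len, index)
    q1 = profile.sample_quality_array(1, 1, rng)[0]
    seq1 = inject_errors(seq1, q1, rng)
    qual1 = (q1 + 33).astype(np.uint8).tobytes().decode()
    if 2 in profile.probabilities:
        q2 = profile.sample_quality_array(2, 1, rng)[0]
        seq2 = inject_errors(seq2, q2, rng)
        qual2 = (q2 + 33).astype(np.uint8).tobytes().decode()
        return ReadPair(name, seq1, qual1, seq2, qual2)
    return ReadPair(name, seq1, qual1)


def _inject_errors_block(
    seqs: np.ndarray, quals: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized error injection on an (n, L) uint8 base matrix (in place)."""
    codes = _BASE_CODE[seqs]
    p = phred_error_prob(quals)
    hit = (rng.random(seqs.shape) < p) & (codes >= 0)
    shift = rng.integers(1, 4, size=seqs.shape)
    seqs[hit] = _CODE_BASE[(codes[hit] + shift[hit]) % 4]
    return seqs


def _generate_chunk(
    alleles: Sequence[AlleleSequence],
    profile: QualityProfile,
    cfg: ReadGenConfig,
    n_pairs: int,
    seed_seq: np.random.SeedSequence,
    start_index: int,
) -> tuple[str, str]:
    """One chunk's worth of reads as (R1 text, R2 text); R2 empty if single-end."""
    rng = np.random.default_rng(seed_seq)
    L = cfg.read_length
    lengths = np.array([len(a.sequence) for a in alleles], dtype=float)
    weights = lengths / lengths.sum()
    if n_pairs == 0:
        return "", ""

    which = rng.choice(len(alleles), size=n_pairs, p=weights)
    if cfg.paired:
        d = np.maximum(np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, n_pairs)), 0)
        frag_lens = (2 * L + d).astype(np.int64)
    else:
        frag_lens = np.full(n_pairs, L, dtype=np.int64)
    allele_lens = lengths[which].astype(np.int64)
    for _ in range(cfg.max_fragment_retries):
        bad = frag_lens > allele_lens
        if not bad.any():
            break
        n_bad = int(bad.sum())
        if cfg.paired:
            d = np.maximum(np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, n_bad)), 0)
            frag_lens[bad] = (2 * L + d).astype(np.int64)
        else:
            raise RuntimeError("allele shorter than read_length")
    else:
        raise RuntimeError("fragment geometry does not fit the shortest allele")
    starts = rng.integers(0, allele_lens - frag_lens + 1)

    flips = (
        rng.random(n_pairs) < 0.5
        if (cfg.paired and cfg.strand_flip)
        else np.zeros(n_pairs, dtype=bool)
    )

    seq1_parts: list[str] = []
    seq2_parts: list[str] = []
    names: list[str] = []
    for i in range(n_pairs):
        a = alleles[which[i]]
        s, fl = int(starts[i]), int(frag_lens[i])
        frag = a.sequence[s : s + fl]
        fwd = frag[:L]
        names.append(make_read_name(a.chrom, a.allele_index, s + 1, s + fl, start_index + i))
        if not cfg.paired:
            seq1_parts.append(fwd)
            continue
        rev = reverse_complement(frag[-L:])
        if flips[i]:
            seq1_parts.append(rev)
            seq2_parts.append(fwd)
        else:
            seq1_parts.append(fwd)
            seq2_parts.append(rev)

    def finish(parts: list[str], mate: int) -> np.ndarray:
        mat = np.frombuffer("".join(parts).encode(), dtype=np.uint8).reshape(n_pairs, L)
        quals = profile.sample_quality_array(mate, n_pairs, rng)
        mat = _inject_errors_block(mat.copy(), quals, rng)
        return mat, (quals + 33).astype(np.uint8)

    mat1, qmat1 = finish(seq1_parts, 1)
    r1_lines: list[str] = []
    r2_lines: list[str] = []
    if cfg.paired:
        mat2, qmat2 = finish(seq2_parts, 2 if 2 in profile.probabilities else 1)
        for i in range(n_pairs):
            r1_lines.append(
                f"@{names[i]}/1\n{mat1[i].tobytes().decode()}\n+\n{qmat1[i].tobytes().decode()}\n"
            )
            r2_lines.append(
                f"@{names[i]}/2\n{mat2[i].tobytes().decode()}\n+\n{qmat2[i].tobytes().decode()}\n"
            )
    else:
        for i in range(n_pairs):
            r1_lines.append(
                f"@{names[i]}\n{mat1[i].tobytes().decode()}\n+\n{qmat1[i].tobytes().decode()}\n"
            )
    return "".join(r1_lines), "".join(r2_lines)


def _open_out(path):
    path = str(path)
    return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")


def generate_reads(
    alleles: Sequence[AlleleSequence],
    profile: QualityProfile,
    cfg: ReadGenConfig,
    out_r1,
    out_r2=None,
) -> int:
    """Generate FASTQ at the configured coverage; returns the pair/read count.

    Output bytes are invariant to ``cfg.workers`` (see module docstring).
    Paired mode writes matched-order R1/R2 files; single-end writes one file.
    """
    alleles = list(alleles)
    if not alleles:
        raise ValueError("no allele sequences supplied")
    if any(len(a.sequence) == 0 for a in alleles):
        raise ValueError("zero-length allele sequence")
    if profile.read_length != cfg.read_length:
        raise ValueError(
            f"profile read_length {profile.read_length} != configured {cfg.read_length}"
        )
    if cfg.paired and out_r2 is None:
        raise ValueError("paired output needs out_r2")

    total_len = sum(len(a.sequence) for a in alleles)
    n_total = compute_pair_count(cfg.coverage, total_len, cfg.read_length, cfg.paired)
    if n_total == 0:
        warnings.warn(
            "requested coverage rounds to zero reads for this genome size",
            stacklevel=2,
        )

    counts = [n_total // N_CHUNKS + (1 if i < n_total % N_CHUNKS else 0) for i in range(N_CHUNKS)]
    offsets = np.concatenate([[0], np.cumsum(counts)])[:-1]
    seeds = np.random.SeedSequence(cfg.seed).spawn(N_CHUNKS)

    def run(i: int) -> tuple[str, str]:
        return _generate_chunk(alleles, profile, cfg, counts[i], seeds[i], int(offsets[i]))

    if cfg.workers > 1:
        with ThreadPoolExecutor(max_workers=cfg.workers) as pool:
            results = list(pool.map(run, range(N_CHUNKS)))
    else:
        results = [run(i) for i in range(N_CHUNKS)]

    with _open_out(out_r1) as f1:
        for r1, _ in results:
            f1.write(r1)
    if cfg.paired:
        with _open_out(out_r2) as f2:
            for _, r2 in results:
                f2.write(r2)
    return n_total
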