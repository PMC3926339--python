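"""Empirical per-cycle base-quality profiles.

The read generator's error model is a per-mate, per-cycle empirical
distribution over Phred scores 0..41 learned from a training FASTQ pair
(Sanger +33 encoding, e.g. 100 bp Illumina data). Quality strings for
simulated reads are drawn one independent sample per cycle from that
cycle's distribution; the substitution-error probability of a base with
score q is the Phred identity 10^(-q/10).

Cycles are modeled as independent: no Markov dependence across cycles and
no conditioning on base identity or GC content.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

MAX_PHRED = 41
N_SCORES = MAX_PHRED + 1


def phred_error_prob(q) -> float | np.ndarray:
    """Substitution error probability for Phred score q: 10^(-q/10)."""
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


@dataclass
class QualityProfile:
    """Per-mate, per-cycle probability vectors over Phred scores 0..41."""

    read_length: int
    probabilities: dict[int, np.ndarray]  # mate -> (read_length, 42)
    training_read_count: dict[int, int] = field(default_factory=dict)
    _cumulative: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        for mate, probs in self.probabilities.items():
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (self.read_length, N_SCORES):
                raise ValueError(
                    f"mate {mate}: expected shape ({self.read_length}, {N_SCORES})"
                )
            sums = probs.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError(f"mate {mate}: per-cycle probabilities must sum to 1")
            self.probabilities[mate] = probs / sums[:, None]

    @property
    def mates(self) -> tuple[int, ...]:
        return tuple(sorted(self.probabilities))

    def _cum(self, mate: int) -> np.ndarray:
        if mate not in self._cumulative:
            self._cumulative[mate] = np.cumsum(self.probabilities[mate], axis=1)
        return self._cumulative[mate]

    def sample_quality_array(
        self, mate: int, n_reads: int, rng: np.random.Generator
    ) -> np.ndarray:
        """(n_reads, read_length) integer Phred scores, one independent draw
        per cycle via inverse-CDF sampling."""
        if mate not in self.probabilities:
            raise ValueError(f"profile has no mate {mate} (mates: {self.mates})")
        cum = self._cum(mate)
        u = rng.random((n_reads, self.read_length))
        scores = np.empty((n_reads, self.read_length), dtype=np.int64)
        for c in range(self.read_length):
            scores[:, c] = np.searchsorted(cum[c], u[:, c], side="right")
        return np.minimum(scores, MAX_PHRED)

    def sample_quality_string(self, mate: int, rng: np.random.Generator) -> str:
        scores = self.sample_quality_array(mate, 1, rng)[0]
        return "".join(chr(33 + int(q)) for q in scores)

    def expected_error_rate(self, mate: int) -> np.ndarray:
        """Per-cycle expected substitution rate: sum_q P(q) * 10^(-q/10)."""
        probs = self.probabilities[mate]
        return probs @ phred_error_prob(np.arange(N_SCORES))

    def to_file(self, path) -> None:
        """Plain-text serialization: header lines then one row per (mate, cycle)."""
        with open(path, "w") as out:
            out.write(f"#read_length\t{self.read_length}\n")
            out.write(f"#mates\t{','.join(str(m) for m in self.mates)}\n")
            counts = ",".join(
                f"{m}:{self.training_read_count.get(m, 0)}" for m in self.mates
            )
            out.write(f"#training_reads\t{counts}\n")
            for mate in self.mates:
                probs = self.probabilities[mate]
                for cycle in range(self.read_length):
                    row = "\t".join(f"{p:.10g}" for p in probs[cycle])
                    out.write(f"{mate}\t{cycle}\t{row}\n")

    @classmethod
    def from_file(cls, path) -> "QualityProfile":
        read_length = None
        counts: dict[int, int] = {}
        rows: dict[int, dict[int, np.ndarray]] = {}
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, value = line[1:].partition("\t")
                    if key == "read_length":
                        read_length = int(value)
                    elif key == "training_reads" and value:
                        for item in value.split(","):
                            m, _, n = item.partition(":")
                            counts[int(m)] = int(n)
                    continue
                fields = line.split("\t")
                mate, cycle = int(fields[0]), int(fields[1])
                probs = np.array([float(x) for x in fields[2:]], dtype=float)
                if probs.size != N_SCORES:
                    raise ValueError(f"{path}: expected {N_SCORES} probabilities per row")
                rows.setdefault(mate, {})[cycle] = probs
        if read_length is None or not rows:
            raise ValueError(f"{path}: not a quality profile file")
        probabilities = {}
        for mate, cycles in rows.items():
            mat = np.zeros((read_length, N_SCORES))
            for cycle, probs in cycles.items():
                mat[cycle] = probs
            probabilities[mate] = mat
        return cls(read_length, probabilities, counts)


def _iter_fastq_qualities(path):
    """Yield (record_id, phred_scores ndarray) from a (gzipped) FASTQ file."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as handle:
        while True:
            header = handle.readline()
            if not header:
                return
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual:
                raise ValueError(f"{path}: truncated FASTQ record at {header.strip()!r}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record at {header.strip()!r}")
            scores = np.frombuffer(qual.strip().encode(), dtype=np.uint8).astype(
                np.int64
            ) - 33
            yield header[1:].split()[0], scores


def build_profile(
    fastq_r1,
    fastq_r2=None,
    read_length: int = 100,
) -> QualityProfile:
    """Train a quality profile from FASTQ: per-cycle Phred histograms.

    Reads longer than ``read_length`` are truncated; shorter reads are
    skipped (their count is recorded on the returned profile as
    ``skipped_read_count``). Scores above 41 indicate a non-Sanger
    encoding and raise, naming the offending record.
    """
    paths = {1: fastq_r1}
    if fastq_r2 is not None:
        paths[2] = fastq_r2
    probabilities: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    skipped: dict[int, int] = {}
    for mate, path in paths.items():
        hist = np.zeros((read_length, N_SCORES), dtype=np.int64)
        used = 0
        skip = 0
        for record_id, scores in _iter_fastq_qualities(path):
            if scores.size < read_length:
                skip += 1
                continue
            scores = scores[:read_length]
            if scores.min() < 0 or scores.max() > MAX_PHRED:
                raise ValueError(
                    f"{path}: record {record_id!r} has Phred scores outside 0..41 "
                    "after +33 decoding (non-Sanger encoding?)"
                )
            hist[np.arange(read_length), scores] += 1
            used += 1
        if used == 0:
            raise ValueError(f"{path}: no usable reads of length >= {read_length}")
        probabilities[mate] = hist / hist.sum(axis=1, keepdims=True)
        counts[mate] = used
        skipped[mate] = skip
    profile = QualityProfile(read_length, probabilities, counts)
    profile.skipped_read_count = skipped
    return profile
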