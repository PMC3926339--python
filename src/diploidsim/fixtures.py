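"""Synthetic fixture generation: reference genomes and training FASTQ.

Every test and evaluation in this package runs on synthetic inputs, so the
generators here are first-class code. They emulate the two external inputs
the simulator needs:

* a reference genome — random ACGT sequence with embedded N-runs at a
  controlled fraction (default 5%, mimicking assembly gaps);
* a paired 100 bp Illumina-like training FASTQ whose per-cycle quality
  distribution is a KNOWN parametric truth (discretized clipped Gaussians
  whose mean decays along the read, mate 2 slightly worse than mate 1), so
  profile-training accuracy can be measured exactly.

What these fixtures do not reproduce about real data: genome composition
bias (GC, repeats), quality dependence on base identity or on the previous
cycle, and indel sequencing errors. Conclusions from tests on fixtures are
about the simulator's own contracts, not about any real instrument.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .quality import MAX_PHRED, N_SCORES, QualityProfile
from .reference import ReferenceGenome

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_reference(
    n_chroms: int = 2,
    chrom_length: int = 1_000_000,
    n_run_fraction: float = 0.05,
    n_run_length: int = 500,
    seed: int = 0,
) -> ReferenceGenome:
    """Random ACGT genome with N-runs covering about ``n_run_fraction`` of it."""
    rng = np.random.default_rng(seed)
    chromosomes: dict[str, str] = {}
    for k in range(1, n_chroms + 1):
        arr = BASES[rng.integers(0, 4, size=chrom_length)].copy()
        if n_run_fraction > 0:
            n_runs = int(round(chrom_length * n_run_fraction / n_run_length))
            for _ in range(n_runs):
                start = int(rng.integers(0, max(1, chrom_length - n_run_length)))
                arr[start : start + n_run_length] = ord("N")
        chromosomes[f"chr{k}"] = arr.tobytes().decode()
    return ReferenceGenome(chromosomes)


def true_quality_distribution(
    read_length: int = 100,
    mate: int = 1,
    q_start: float = 38.0,
    q_end: float = 30.0,
    sd: float = 3.0,
    mate2_penalty: float = 2.0,
) -> np.ndarray:
    """Exact per-cycle Phred distribution of the synthetic training data.

    Cycle c's score is a Gaussian with mean decaying linearly from
    ``q_start`` to ``q_end``, rounded to the nearest integer and clipped to
    0..41; mate 2's mean sits ``mate2_penalty`` lower. Returns the
    (read_length, 42) matrix of exact discrete probabilities.
    """
    cycles = np.arange(read_length)
    mu = q_start + (q_end - q_start) * cycles / max(read_length - 1, 1)
    if mate == 2:
        mu = mu - mate2_penalty
    edges = np.arange(N_SCORES + 1) - 0.5  # bin q gets (q-0.5, q+0.5]
    cdf = norm.cdf(edges[None, :], loc=mu[:, None], scale=sd)
    probs = np.diff(cdf, axis=1)
    probs[:, 0] += cdf[:, 0]  # mass below -0.5 clips to 0
    probs[:, -1] += 1.0 - cdf[:, -1]  # mass above 41.5 clips to 41
    return probs / probs.sum(axis=1, keepdims=True)


def synthetic_profile(read_length: int = 100, paired: bool = True, **kwargs) -> QualityProfile:
    """A :class:`QualityProfile` holding the exact synthetic truth distributions."""
    probabilities = {1: true_quality_distribution(read_length, mate=1, **kwargs)}
    if paired:
        probabilities[2] = true_quality_distribution(read_length, mate=2, **kwargs)
    return QualityProfile(read_length, probabilities)


def make_training_fastq(
    path_r1,
    path_r2=None,
    n_reads: int = 10_000,
    read_length: int = 100,
    seed: int = 0,
    **dist_kwargs,
) -> None:
    """Write synthetic Sanger-encoded training FASTQ drawn from the known
    per-cycle quality distribution (random ACGT bases)."""
    rng = np.random.default_rng(seed)
    mates = [(1, path_r1)] + ([(2, path_r2)] if path_r2 is not None else [])
    for mate, path in mates:
        probs = true_quality_distribution(read_length, mate=mate, **dist_kwargs)
        cum = np.cumsum(probs, axis=1)
        base_mat = BASES[rng.integers(0, 4, size=(n_reads, read_length))]
        u = rng.random((n_reads, read_length))
        scores = np.empty((n_reads, read_length), dtype=np.int64)
        for c in range(read_length):
            scores[:, c] = np.searchsorted(cum[c], u[:, c], side="right")
        qual_mat = (np.minimum(scores, MAX_PHRED) + 33).astype(np.uint8)
        with open(path, "w") as out:
            for i in range(n_reads):
                out.write(
                    f"@train_{mate}_{i}\n{base_mat[i].tobytes().decode()}\n+\n"
                    f"{qual_mat[i].tobytes().decode()}\n"
                )
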