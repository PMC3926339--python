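"""Read generation: coverage accounting, pairing, errors, parallel contract."""

import math

import numpy as np
import pytest

from diploidsim.quality import N_SCORES, QualityProfile
from diploidsim.reads import (
    ReadGenConfig,
    compute_pair_count,
    decode_read_name,
    draw_fragment,
    generate_reads,
    inject_errors,
    make_read_pair,
    reverse_complement,
)
from diploidsim.reference import ReferenceGenome, apply_variants


def _point_profile(read_length=100, q=40, paired=True):
    probs = np.zeros((read_length, N_SCORES))
    probs[:, q] = 1.0
    mates = {1: probs}
    if paired:
        mates[2] = probs.copy()
    return QualityProfile(read_length, mates)


def _alleles(seq, n_chroms=1):
    g = ReferenceGenome({f"chr{k}": seq for k in range(1, n_chroms + 1)})
    out = []
    for idx in (1, 2):
        out.extend(apply_variants(g, allele_index=idx).values())
    return out


def _read_fastq(path):
    lines = path.read_text().splitlines()
    return [
        (lines[i][1:], lines[i + 1], lines[i + 3]) for i in range(0, len(lines), 4)
    ]


class TestComputePairCount:
    def test_coverage_identity_paired(self):
        assert compute_pair_count(15, 2_000_000, 100, paired=True) == 150_000

    def test_coverage_identity_single(self):
        assert compute_pair_count(15, 2_000_000, 100, paired=False) == 300_000

    def test_rounds_to_zero(self):
        assert compute_pair_count(0.0001, 10_000, 100, paired=True) == 0


class TestDrawFragment:
    def test_degenerate_insert(self, rng):
        cfg = ReadGenConfig(coverage=1, insert_mean=100, insert_sd=0)
        for _ in range(20):
            start, frag_len = draw_fragment(10_000, cfg, rng)
            assert frag_len == 300
            assert 0 <= start <= 10_000 - 300

    def test_exact_fit_start_zero(self, rng):
        cfg = ReadGenConfig(coverage=1, insert_mean=100, insert_sd=0)
        assert draw_fragment(300, cfg, rng) == (0, 300)

    def test_too_small_allele_errors(self, rng):
        cfg = ReadGenConfig(coverage=1, insert_mean=100, insert_sd=0,
                            max_fragment_retries=5)
        with pytest.raises(RuntimeError):
            draw_fragment(250, cfg, rng)

    def test_inner_distance_mean(self, rng):
        cfg = ReadGenConfig(coverage=1, insert_mean=150, insert_sd=20)
        ds = [draw_fragment(100_000, cfg, rng)[1] - 200 for _ in range(20_000)]
        se = 20 / math.sqrt(len(ds))
        assert abs(np.mean(ds) - 150) < 3 * se


class TestMakeReadPair:
    def test_forward_and_reverse_complement(self, rng):
        alleles = _alleles("A" * 300)
        pair = make_read_pair(alleles[0], (0, 300), _point_profile(), rng)
        assert pair.seq1 == "A" * 100
        assert pair.seq2 == "T" * 100

    def test_n_passthrough_never_corrected(self, rng):
        # N bases survive even with the worst possible quality (p_error = 1)
        alleles = _alleles("N" * 300)
        pair = make_read_pair(alleles[0], (0, 300), _point_profile(q=0), rng)
        assert pair.seq1 == "N" * 100 and pair.seq2 == "N" * 100

    def test_name_decodes_fragment(self, rng):
        alleles = _alleles("ACGT" * 100)
        pair = make_read_pair(alleles[1], (17, 350), _point_profile(), rng, index=9)
        chrom, allele, start, end, index = decode_read_name(pair.name)
        assert (chrom, allele, start, end, index) == ("chr1", 2, 18, 367, 9)


class TestInjectErrors:
    def test_p_one_forces_substitution_everywhere(self, rng):
        out = inject_errors("AAAA", np.zeros(4, dtype=int), rng)
        assert "A" not in out and set(out) <= set("CGT")

    def test_high_quality_rate(self, rng):
        # binomial oracle: per-base error rate 10^(-4.1) at Q41
        n, L = 10_000, 100
        errors = 0
        for _ in range(n):
            out = inject_errors("A" * L, np.full(L, 41), rng)
            errors += sum(c != "A" for c in out)
        p = 10 ** (-4.1)
        se = math.sqrt(p * (1 - p) * n * L)
        assert abs(errors - p * n * L) < 3 * se


class TestGenerateReads:
    def test_worker_count_byte_invariance(self, tmp_path, profile100):
        alleles = _alleles("ACGT" * 5_000)  # 20 kb x 2 alleles
        outputs = {}
        for workers in (1, 4):
            cfg = ReadGenConfig(coverage=5, workers=workers, seed=11)
            r1, r2 = tmp_path / f"w{workers}_1.fq", tmp_path / f"w{workers}_2.fq"
            generate_reads(alleles, profile100, cfg, r1, r2)
            outputs[workers] = (r1.read_bytes(), r2.read_bytes())
        assert outputs[1] == outputs[4]

    def test_r1_r2_matched_names_and_counts(self, tmp_path, profile100):
        alleles = _alleles("ACGT" * 5_000)
        cfg = ReadGenConfig(coverage=2, seed=3)
        r1, r2 = tmp_path / "a_1.fq", tmp_path / "a_2.fq"
        n = generate_reads(alleles, profile100, cfg, r1, r2)
        recs1, recs2 = _read_fastq(r1), _read_fastq(r2)
        assert len(recs1) == len(recs2) == n
        for (n1, s1, q1), (n2, s2, q2) in zip(recs1, recs2):
            assert n1[:-2] == n2[:-2] and n1.endswith("/1") and n2.endswith("/2")
            assert len(s1) == len(q1) == 100

    def test_coverage_accounting_within_one_percent(self, tmp_path, profile100):
        alleles = _alleles("ACGT" * 25_000)  # 100 kb per allele
        total_len = sum(len(a.sequence) for a in alleles)
        cfg = ReadGenConfig(coverage=10, seed=4)
        r1, r2 = tmp_path / "c_1.fq", tmp_path / "c_2.fq"
        generate_reads(alleles, profile100, cfg, r1, r2)
        emitted = sum(len(s) for _, s, _ in _read_fastq(r1))
        emitted += sum(len(s) for _, s, _ in _read_fastq(r2))
        assert abs(emitted / total_len - 10) / 10 < 0.01

    def test_single_end_one_file_no_mate_suffix(self, tmp_path):
        alleles = _alleles("ACGT" * 5_000)
        profile = _point_profile(paired=False)
        cfg = ReadGenConfig(coverage=1, paired=False, seed=5)
        r1 = tmp_path / "se.fq"
        n = generate_reads(alleles, profile, cfg, r1)
        recs = _read_fastq(r1)
        assert len(recs) == n
        assert all("/" not in name for name, _, _ in recs)

    def test_fragments_lie_inside_their_allele(self, tmp_path, profile100):
        alleles = _alleles("ACGT" * 2_500)
        cfg = ReadGenConfig(coverage=3, seed=6)
        r1, r2 = tmp_path / "f_1.fq", tmp_path / "f_2.fq"
        generate_reads(alleles, profile100, cfg, r1, r2)
        lengths = {(a.chrom, a.allele_index): len(a.sequence) for a in alleles}
        for name, _, _ in _read_fastq(r1):
            chrom, allele, start, end, _ = decode_read_name(name)
            assert 1 <= start <= end <= lengths[(chrom, allele)]

    def test_profile_length_mismatch_rejected(self, tmp_path, profile100):
        alleles = _alleles("ACGT" * 5_000)
        cfg = ReadGenConfig(coverage=1, read_length=50, seed=7)
        with pytest.raises(ValueError, match="read_length"):
            generate_reads(alleles, profile100, cfg, tmp_path / "x_1.fq", tmp_path / "x_2.fq")

    def test_hom_cnv_gain_doubles_depth(self, tmp_path):
        """End-to-end depth signal: a homozygous copy-2 gain shows ~2x depth.

        Depth is computed alignment-free from the provenance names mapped
        back through the coordinate map.
        """
        from diploidsim.cnv import CNVRecord
        from diploidsim.fixtures import make_reference

        genome = make_reference(1, 200_000, n_run_fraction=0.0, seed=8)
        gain = CNVRecord("chr1", 50_001, 70_000, 2, 2)
        alleles = []
        for idx in (1, 2):
            alleles.extend(apply_variants(genome, cnvs=[gain], allele_index=idx).values())
        cfg = ReadGenConfig(coverage=30, seed=9)
        r1, r2 = tmp_path / "d_1.fq", tmp_path / "d_2.fq"
        generate_reads(alleles, _point_profile(), cfg, r1, r2)

        # per-allele-base depth from fragment spans (both mates = 2*L bases)
        depth = np.zeros(len(alleles[0].sequence))
        for name, _, _ in _read_fastq(r1):
            chrom, allele, start, end, _ = decode_read_name(name)
            depth[start - 1 : start + 99] += 1
            depth[end - 100 : end] += 1
        # project allele depth back to reference coordinates: the two tandem
        # copies of the gained span both map onto ref [50001, 70000]
        gain_lo = alleles[0].coord_map(50_000)
        ref_depth_gain = (
            depth[gain_lo : gain_lo + 20_000] + depth[gain_lo + 20_000 : gain_lo + 40_000]
        ).mean()
        flank = np.concatenate([depth[10_000:40_000], depth[150_000:200_000]]).mean()
        assert ref_depth_gain / flank == pytest.approx(2.0, rel=0.25)


def test_reverse_complement():
    assert reverse_complement("ACGTN") == "NACGT"
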