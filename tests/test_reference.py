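"""Reference I/O, N-region detection, and allele realization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diploidsim.cnv import CNVRecord
from diploidsim.indels import IndelRecord
from diploidsim.reference import (
    FastaParseError,
    ReferenceGenome,
    apply_variants,
    find_n_regions,
    normalize_sequence,
    read_fasta,
    write_fasta,
)
from diploidsim.snv import SNVRecord


def _write(tmp_path, text, name="ref.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_parses_and_locates_n_region(self, tmp_path):
        g = read_fasta(_write(tmp_path, ">chr1\nACGTN\n"))
        assert g.chromosomes == {"chr1": "ACGTN"}
        assert g.n_regions == {"chr1": [(4, 5)]}

    def test_lowercase_normalized_uppercase(self, tmp_path):
        g = read_fasta(_write(tmp_path, ">chr1\nacgt\n"))
        assert g.chromosomes["chr1"] == "ACGT"
        assert g.n_regions["chr1"] == []

    def test_wrapped_lines_joined(self, tmp_path):
        g = read_fasta(_write(tmp_path, ">chr1\nAC\nGT\n"))
        assert g.chromosomes["chr1"] == "ACGT"

    def test_iupac_ambiguity_becomes_n(self, tmp_path):
        g = read_fasta(_write(tmp_path, ">chr1\nARYT\n"))
        assert g.chromosomes["chr1"] == "ANNT"
        assert g.n_regions["chr1"] == [(1, 3)]

    def test_duplicate_chromosome_rejected(self, tmp_path):
        with pytest.raises(FastaParseError, match="duplicate"):
            read_fasta(_write(tmp_path, ">chr1\nAC\n>chr1\nGT\n"))

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(FastaParseError):
            read_fasta(_write(tmp_path, ""))


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("ACGT", []),
        ("NNACNN", [(0, 2), (4, 6)]),
        ("N" * 10, [(0, 10)]),
        ("", []),
        ("NACGTN", [(0, 1), (5, 6)]),
    ],
)
def test_find_n_regions(seq, expected):
    assert find_n_regions(seq) == expected


def test_n_regions_exactly_cover_non_acgt():
    seq = normalize_sequence("acGTnnRYacNN")
    regions = find_n_regions(seq)
    covered = {i for a, b in regions for i in range(a, b)}
    assert covered == {i for i, c in enumerate(seq) if c not in "ACGT"}


class TestApplyVariants:
    def test_homozygous_snv_substituted(self):
        g = ReferenceGenome({"chr1": "ACGTACGT"})
        snv = SNVRecord("chr1", 3, "G", "A", "hom", "both", True)
        alleles = apply_variants(g, snvs=[snv], allele_index=1)
        assert alleles["chr1"].sequence == "ACATACGT"

    def test_het_snv_only_on_its_allele(self):
        g = ReferenceGenome({"chr1": "ACGT"})
        snv = SNVRecord("chr1", 1, "A", "T", "het", 2, False)
        assert apply_variants(g, snvs=[snv], allele_index=1)["chr1"].sequence == "ACGT"
        assert apply_variants(g, snvs=[snv], allele_index=2)["chr1"].sequence == "TCGT"

    def test_deletion_and_coord_map(self):
        g = ReferenceGenome({"chr1": "ACGT"})
        rec = IndelRecord("chr1", 2, "deletion", 2, "CG", "mid", "hom", "both")
        allele = apply_variants(g, indels=[rec], allele_index=1)["chr1"]
        assert allele.sequence == "AT"
        # 1-based ref position 4 maps to 1-based allele position 2
        assert allele.coord_map(4 - 1) == 2 - 1
        # deleted positions map to the deletion's left edge
        assert allele.coord_map(1) == 1
        assert allele.coord_map(2) == 1

    def test_insertion_after_anchor(self):
        g = ReferenceGenome({"chr1": "ACGT"})
        rec = IndelRecord("chr1", 2, "insertion", 2, "TT", "mid", "hom", "both")
        allele = apply_variants(g, indels=[rec], allele_index=1)["chr1"]
        assert allele.sequence == "ACTTGT"

    def test_cnv_gain_tandem_duplication(self):
        # independent oracle: concatenate copy_number copies of the span in place
        g = ReferenceGenome({"chr1": "ACGT"})
        rec = CNVRecord("chr1", 1, 2, 3, 1)
        allele = apply_variants(g, cnvs=[rec], allele_index=1)["chr1"]
        assert allele.sequence == "AC" * 3 + "GT"
        assert apply_variants(g, cnvs=[rec], allele_index=2)["chr1"].sequence == "ACGT"

    def test_cnv_loss_removes_span(self):
        g = ReferenceGenome({"chr1": "ACGTAC"})
        rec = CNVRecord("chr1", 2, 4, 0, 0)
        assert apply_variants(g, cnvs=[rec], allele_index=1)["chr1"].sequence == "AAC"

    def test_snv_nested_in_cnv_gain_mutates_every_copy(self):
        g = ReferenceGenome({"chr1": "ACGT"})
        snv = SNVRecord("chr1", 2, "C", "T", "hom", "both", True)
        cnv = CNVRecord("chr1", 1, 2, 2, 1)
        allele = apply_variants(g, snvs=[snv], cnvs=[cnv], allele_index=1)["chr1"]
        assert allele.sequence == "ATATGT"

    def test_empty_variant_list_is_identity(self):
        g = ReferenceGenome({"chr1": "ACGTNNGT"})
        allele = apply_variants(g, allele_index=1)["chr1"]
        assert allele.sequence == g.chromosomes["chr1"]
        assert all(allele.coord_map(i) == i for i in range(len(allele.sequence)))

    def test_overlapping_deletions_rejected(self):
        g = ReferenceGenome({"chr1": "ACGTACGT"})
        recs = [
            IndelRecord("chr1", 2, "deletion", 3, "CGT", "mid", "hom", "both"),
            IndelRecord("chr1", 3, "deletion", 2, "GT", "mid", "hom", "both"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            apply_variants(g, indels=recs, allele_index=1)

    def test_variant_outside_chromosome_rejected(self):
        g = ReferenceGenome({"chr1": "ACGT"})
        rec = IndelRecord("chr1", 4, "deletion", 5, "XXXXX", "mid", "hom", "both")
        with pytest.raises(ValueError):
            apply_variants(g, indels=[rec], allele_index=1)

    @given(
        n_ins=st.integers(0, 3),
        n_del=st.integers(0, 3),
        cn=st.integers(0, 4),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_length_accounting(self, n_ins, n_del, cn, data):
        """allele length = ref + inserted - deleted - lost + (cn-1)*gain span."""
        seq = "ACGT" * 300
        g = ReferenceGenome({"chr1": seq})
        indels, expected = [], len(seq)
        # non-overlapping slots: indels in [1, 400], CNV far right
        slots = sorted(
            data.draw(
                st.lists(
                    st.integers(1, 40), min_size=n_ins + n_del,
                    max_size=n_ins + n_del, unique=True,
                )
            )
        )
        for k, slot in enumerate(slots):
            pos = slot * 10
            if k < n_ins:
                length = data.draw(st.integers(1, 5))
                indels.append(
                    IndelRecord("chr1", pos, "insertion", length, "A" * length, "mid", "hom", "both")
                )
                expected += length
            else:
                length = data.draw(st.integers(1, 5))
                indels.append(
                    IndelRecord("chr1", pos, "deletion", length,
                                seq[pos - 1 : pos - 1 + length], "mid", "hom", "both")
                )
                expected -= length
        cnvs = []
        if cn != 1:
            cnvs = [CNVRecord("chr1", 600, 699, cn, cn)]
            expected += (cn - 1) * 100
        allele = apply_variants(g, indels=indels, cnvs=cnvs, allele_index=1)["chr1"]
        assert len(allele.sequence) == expected
        assert allele.coord_map.allele_length_delta == expected - len(seq)


class TestWriteFasta:
    def test_roundtrip_recovers_sequences(self, tmp_path, small_genome):
        alleles = apply_variants(small_genome, allele_index=1)
        path = tmp_path / "alleles.fasta"
        write_fasta(alleles.values(), path)
        back = read_fasta(path)
        for chrom, seq in small_genome.chromosomes.items():
            assert back.chromosomes[f"{chrom}_allele1"] == seq

    def test_header_and_body(self, tmp_path):
        g = ReferenceGenome({"chr1": "ACGT"})
        allele = apply_variants(g, allele_index=1)["chr1"]
        path = tmp_path / "one.fasta"
        write_fasta([allele], path)
        assert path.read_text() == ">chr1_allele1\nACGT\n"

    def test_empty_list_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        write_fasta([], path)
        assert path.read_text() == ""

    def test_wrapping_at_width(self, tmp_path):
        g = ReferenceGenome({"chr1": "A" * 150})
        allele = apply_variants(g, allele_index=1)["chr1"]
        path = tmp_path / "wrap.fasta"
        write_fasta([allele], path, width=70)
        lines = path.read_text().splitlines()
        assert [len(x) for x in lines[1:]] == [70, 70, 10]
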