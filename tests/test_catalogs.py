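"""Channel classification, matrix construction and I/O."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigkit.catalogs import (
    MutationRecord,
    MutationalMatrix,
    RecordError,
    annotate_context,
    build_matrix,
    classify_sbs,
    collapse_matrix,
    read_mutation_table,
    read_vcf,
)
from sigkit.schemas import BASES, COMPLEMENT, PYRIMIDINES, SBS96, SBS288, SBS1536, revcomp


def rec(ref, alt, penta, strand="non_transcribed", sample="s1"):
    return MutationRecord(sample, "chr1", 100, ref, alt, penta, strand)


class TestClassify:
    @pytest.mark.parametrize(
        "ref,alt,penta,schema,expected",
        [
            ("C", "T", "AACAA", "SBS96", "A[C>T]A"),
            # purine reference: revcomp(TTGGA)=TCCAA, center C>T, flanks C/A
            ("G", "A", "TTGGA", "SBS96", "C[C>T]A"),
            ("C", "A", "AACAA", "SBS96", "A[C>A]A"),
            ("C", "A", "AACAA", "SBS1536", "AA[C>A]AA"),
            ("G", "A", "TTGGA", "SBS1536", "TC[C>T]AA"),
        ],
    )
    def test_channel_labels(self, ref, alt, penta, schema, expected):
        assert classify_sbs(rec(ref, alt, penta), schema) == expected

    @pytest.mark.parametrize(
        "strand,ref,expected_prefix",
        [
            ("non_transcribed", "C", "N"),
            ("gene_both", "C", "N"),
            # gene on '+': reference-strand pyrimidine sits on the coding strand
            ("gene_forward", "C", "U"),
            ("gene_reverse", "C", "T"),
            # purine reference: the pyrimidine is on the '-' strand
            ("gene_forward", "G", "T"),
            ("gene_reverse", "G", "U"),
        ],
    )
    def test_sbs288_strand_prefix(self, strand, ref, expected_prefix):
        penta = "AACAA" if ref == "C" else "TTGTT"
        alt = "T" if ref == "C" else "A"
        label = classify_sbs(rec(ref, alt, penta, strand), "SBS288")
        assert label.startswith(expected_prefix + ":")

    def test_strand_complement_involution(self):
        """Reverse-complementing a record (and flipping its gene orientation)
        never changes its channel, for all 6 x 16 trinucleotide cases."""
        flip_strand = {
            "gene_forward": "gene_reverse",
            "gene_reverse": "gene_forward",
            "non_transcribed": "non_transcribed",
        }
        for pyr, alt in [("C", a) for a in "AGT"] + [("T", a) for a in "ACG"]:
            for five, three in itertools.product(BASES, BASES):
                penta = f"A{five}{pyr}{three}A"
                for strand in flip_strand:
                    fwd = rec(pyr, alt, penta, strand)
                    bwd = rec(
                        COMPLEMENT[pyr],
                        COMPLEMENT[alt],
                        revcomp(penta),
                        flip_strand[strand],
                    )
                    for schema in (SBS96, SBS288, SBS1536):
                        assert classify_sbs(fwd, schema) == classify_sbs(bwd, schema)

    def test_ambiguous_context_rejected(self):
        with pytest.raises(RecordError, match="ambiguous"):
            classify_sbs(rec("C", "T", "ANCAA"), "SBS96")
        # outer-flank N only matters for the pentanucleotide schema
        assert classify_sbs(rec("C", "T", "NACAA"), "SBS96") == "A[C>T]A"
        with pytest.raises(RecordError, match="ambiguous"):
            classify_sbs(rec("C", "T", "NACAA"), "SBS1536")

    def test_context_mismatch_rejected(self):
        with pytest.raises(RecordError, match="context_ref_mismatch"):
            classify_sbs(rec("C", "T", "AATAA"), "SBS96")

    @given(
        pyr=st.sampled_from("CT"),
        flanks=st.tuples(*[st.sampled_from("ACGT")] * 4),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_classification_lands_in_schema(self, pyr, flanks, data):
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != pyr]))
        penta = f"{flanks[0]}{flanks[1]}{pyr}{flanks[2]}{flanks[3]}"
        for schema in (SBS96, SBS288, SBS1536):
            assert classify_sbs(rec(pyr, alt, penta), schema) in schema.channel_labels


class TestBuildMatrix:
    @pytest.mark.parametrize(
        "schema,n_rows", [(SBS96, 96), (SBS288, 288), (SBS1536, 1536)]
    )
    def test_channel_count_law(self, schema, n_rows):
        records = [rec("C", "T", "AACAA"), rec("G", "A", "TTGGA", sample="s2")]
        m = build_matrix(records, schema)
        assert m.counts.shape[0] == n_rows
        assert int(m.counts.to_numpy().sum()) == len(records)

    def test_empty_records_with_declared_samples(self):
        m = build_matrix([], SBS96, sample_ids=["s1"])
        assert m.counts.shape == (96, 1)
        assert int(m.counts.to_numpy().sum()) == 0

    def test_rejections_counted_not_fatal(self):
        records = [rec("C", "T", "AACAA"), rec("C", "T", "ANCAA")]
        m = build_matrix(records, SBS96)
        assert int(m.counts.to_numpy().sum()) == 1
        assert m.rejections["ambiguous_context"] == 1


class TestCollapse:
    def test_strand_categories_sum(self):
        records = (
            [rec("C", "A", "AACAA", "gene_reverse")] * 2  # T:
            + [rec("C", "A", "AACAA", "gene_forward")] * 3  # U:
            + [rec("C", "A", "AACAA", "non_transcribed")] * 5  # N:
        )
        m288 = build_matrix(records, SBS288)
        assert m288.counts.at["T:A[C>A]A", "s1"] == 2
        assert m288.counts.at["U:A[C>A]A", "s1"] == 3
        assert m288.counts.at["N:A[C>A]A", "s1"] == 5
        m96 = collapse_matrix(m288)
        assert m96.counts.at["A[C>A]A", "s1"] == 10

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_collapse_commutes_with_aggregation(self, seed):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(rng.integers(5, 40)):
            pyr = rng.choice(["C", "T"])
            alt = rng.choice([b for b in "ACGT" if b != pyr])
            penta = "".join(rng.choice(list(BASES), 5))
            penta = penta[:2] + pyr + penta[3:]
            strand = rng.choice(
                ["non_transcribed", "gene_forward", "gene_reverse", "gene_both"]
            )
            r = rec(pyr, alt, penta, strand, sample=f"s{rng.integers(3)}")
            if rng.random() < 0.5:  # represent on the purine strand
                r = rec(
                    COMPLEMENT[pyr], COMPLEMENT[alt], revcomp(penta), strand,
                    sample=r.sample_id,
                )
            records.append(r)
        samples = sorted({r.sample_id for r in records})
        for big in (SBS288, SBS1536):
            direct = build_matrix(records, SBS96, sample_ids=samples)
            collapsed = collapse_matrix(build_matrix(records, big, sample_ids=samples))
            pd.testing.assert_frame_equal(direct.counts, collapsed.counts)

    def test_collapse_preserves_column_totals(self, small_cohort):
        m = small_cohort.catalog
        assert collapse_matrix(m).column_sums().equals(m.column_sums())


class TestIO:
    def test_tsv_roundtrip(self, tmp_path, small_cohort):
        path = tmp_path / "m.tsv"
        small_cohort.catalog.to_tsv(path)
        back = MutationalMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(back.counts, small_cohort.catalog.counts)

    def test_read_mutation_table(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text(
            "sample\tchrom\tpos\tref\talt\tpentacontext\tstrand_status\n"
            "s1\tchr1\t100\tC\tT\tAACAA\tnon_transcribed\n"
            "s1\tchr1\t200\tG\tA\tTTGGA\tgene_forward\n"
            "s2\tchr2\t300\tT\tG\tCCTGG\tgene_reverse\n"
        )
        records = read_mutation_table(path)
        assert len(records) == 3
        assert not records.rejections

    def test_reader_rejects_context_mismatch(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text(
            "sample\tchrom\tpos\tref\talt\tpentacontext\tstrand_status\n"
            "s1\tchr1\t100\tC\tT\tAATAA\tnon_transcribed\n"
            "s1\tchr1\t200\tC\tT\tAACAA\tnon_transcribed\n"
        )
        records = read_mutation_table(path)
        assert len(records) == 1
        assert records.rejections["context_ref_mismatch"] == 1

    def test_reader_missing_column_fatal(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text("sample\tchrom\tpos\tref\talt\tpentacontext\ns1\t1\t5\tC\tT\tAACAA\n")
        with pytest.raises(ValueError, match="strand_status"):
            read_mutation_table(path)

    def test_optional_annotations_parsed(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text(
            "sample\tchrom\tpos\tref\talt\tpentacontext\tstrand_status\t"
            "ccf\tmultiplicity\tmajor_cn\tminor_cn\n"
            "s1\tchr1\t100\tC\tT\tAACAA\tnon_transcribed\t0.99\t2\t3\t1\n"
            "s1\tchr1\t200\tC\tT\tAACAA\tnon_transcribed\t\t\t\t\n"
        )
        records = read_mutation_table(path)
        assert records[0].ccf == 0.99 and records[0].multiplicity == 2
        assert records[1].ccf is None and records[1].major_cn is None


class TestAnnotateContext:
    def _fasta(self, tmp_path, seq="AAACAAA", name="chr1"):
        path = tmp_path / "toy.fa"
        path.write_text(f">{name}\n{seq}\n")
        return path

    def test_toy_contig(self, tmp_path):
        fa = self._fasta(tmp_path)
        out = annotate_context(
            [MutationRecord("s1", "chr1", 4, "C", "T")], fa
        )
        assert out[0].pentacontext == "AACAA"

    def test_edge_margin_rejected(self, tmp_path):
        fa = self._fasta(tmp_path)
        out = annotate_context([MutationRecord("s1", "chr1", 2, "A", "T")], fa)
        assert len(out) == 0
        assert out.rejections["contig_edge"] == 1

    def test_softmasked_uppercased(self, tmp_path):
        fa = self._fasta(tmp_path, seq="aaacaaa")
        out = annotate_context([MutationRecord("s1", "chr1", 4, "C", "T")], fa)
        assert out[0].pentacontext == "AACAA"

    def test_existing_context_must_agree(self, tmp_path):
        fa = self._fasta(tmp_path)
        out = annotate_context(
            [MutationRecord("s1", "chr1", 4, "C", "T", pentacontext="GGCGG")], fa
        )
        assert len(out) == 0
        assert out.rejections["context_disagreement"] == 1


class TestVCF:
    def test_pass_only_and_multiallelic_split(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FILTER=<ID=lowq,Description="low quality">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tC\tT\t.\tPASS\t.\n"
            "chr1\t200\t.\tG\tA,T\t.\tPASS\t.\n"
            "chr1\t300\t.\tC\tT\t.\tlowq\t.\n"
            "chr1\t400\t.\tCT\tC\t.\tPASS\t.\n"
        )
        records = read_vcf(vcf, sample_id="s1")
        assert len(records) == 3  # 1 + 2 split alleles
        assert records.rejections["non_pass"] == 1
        assert records.rejections["not_sbs"] == 1
        assert {r.pos for r in records} == {100, 200}
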