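"""Feature transfer, UTR subcategorisation and sRNA classification."""

from __future__ import annotations

import pytest

from rendannot.features import (
    AnnotationRecord,
    CDS,
    CdsConsistencyError,
    FIVE_UTR,
    FIVE_UTR_DERIVED,
    GENERIC,
    INDEPENDENT_WITH_ISOFORM,
    INDEPENDENT_WITHOUT_ISOFORM,
    INTERGENIC,
    INTRAGENIC,
    NOVEL,
    PUTATIVE_SRNA,
    THREE_UTR,
    THREE_UTR_DERIVED,
    classify_srna,
    read_annotation,
    subcategorize_cds,
    transfer_features,
)
from rendannot.operons import Operon
from rendannot.transcripts import Transcript


def _t(left, right, strand="+"):
    return Transcript(left=left, right=right, strand=strand)


def _cds(left, right, strand="+", name="gene"):
    return AnnotationRecord(left=left, right=right, strand=strand, feature=CDS, name=name)


class TestTransferFeatures:
    def test_contained_cds_transcript_inherits_name(self):
        t = _t(100, 1000)
        transfer_features([t], [_cds(125, 960, name="abc")])
        assert t.feature == CDS
        assert t.attributes["Name"] == "abc"

    def test_no_overlap_is_novel(self):
        t = _t(5000, 5400)
        transfer_features([t], [_cds(100, 900)])
        assert t.feature == NOVEL

    def test_antisense_overlap_counts_as_no_overlap(self):
        t = _t(100, 1000, strand="-")
        transfer_features([t], [_cds(125, 960, strand="+")])
        assert t.feature == NOVEL

    def test_single_class_partial_overlap_inherits_class(self):
        t = _t(500, 1200)
        transfer_features([t], [_cds(100, 900)])
        assert t.feature == CDS  # 3'-portion ORF overlap keeps the CDS label

    def test_multiple_classes_give_generic_label(self):
        t = _t(100, 1000)
        records = [
            _cds(50, 500),
            AnnotationRecord(left=800, right=950, strand="+", feature="sRNA", name="s1"),
        ]
        transfer_features([t], records)
        assert t.feature == GENERIC

    def test_every_transcript_gets_exactly_one_label(self):
        records = [
            _cds(100, 900, name="g1"),
            AnnotationRecord(left=2000, right=2100, strand="+", feature="sRNA", name="s1"),
            AnnotationRecord(left=3000, right=3070, strand="+", feature="tRNA", name="t1"),
        ]
        transcripts = [
            _t(50, 950), _t(1990, 2110), _t(2990, 3080), _t(5000, 5100),
            _t(880, 2050),
        ]
        transfer_features(transcripts, records)
        labels = [t.feature for t in transcripts]
        assert labels == [CDS, "sRNA", "tRNA", NOVEL, GENERIC]

    def test_container_records_ignored(self):
        t = _t(100, 1000)
        records = [
            _cds(125, 960),
            AnnotationRecord(left=1, right=5000, strand="+", feature="operon"),
            AnnotationRecord(left=100, right=1000, strand="+", feature="gene"),
        ]
        transfer_features([t], records)
        assert t.feature == CDS


class TestSubcategorizeCds:
    def test_utr_lengths_25_and_40(self):
        t = _t(100, 1000)
        t.feature = CDS
        records = subcategorize_cds(t, [_cds(125, 960)])
        assert [(r.feature, r.left, r.right) for r in records] == [
            (FIVE_UTR, 100, 124),
            (CDS, 125, 960),
            (THREE_UTR, 961, 1000),
        ]
        assert records[0].length == 25
        assert records[2].length == 40

    def test_zero_length_utr_omitted(self):
        t = _t(125, 1000)
        records = subcategorize_cds(t, [_cds(125, 960)])
        assert [r.feature for r in records] == [CDS, THREE_UTR]

    def test_polycistronic_tiles_transcript(self):
        t = _t(100, 2000)
        cds = [_cds(150, 800, name="g1"), _cds(900, 1900, name="g2")]
        records = subcategorize_cds(t, cds)
        assert [r.feature for r in records] == [FIVE_UTR, CDS, CDS, THREE_UTR]
        # spans tile the transcript; intercistronic gap stays inside the CDS block
        assert records[0].left == t.left
        assert records[-1].right == t.right
        covered = records[0].length + (records[-2].right - records[1].left + 1) + records[-1].length
        assert covered == t.length

    def test_minus_strand_utrs_swap_sides(self):
        t = _t(100, 1000, strand="-")
        records = subcategorize_cds(t, [_cds(125, 960, strand="-")])
        assert records[0].feature == FIVE_UTR
        assert (records[0].left, records[0].right) == (961, 1000)
        assert (records[-1].left, records[-1].right) == (100, 124)

    def test_cds_beyond_span_raises(self):
        t = _t(200, 1000)
        with pytest.raises(CdsConsistencyError):
            subcategorize_cds(t, [_cds(125, 960)])


class TestClassifySrna:
    def test_truncated_transcript_covering_start_codon_is_putative(self):
        # transcript runs from the mRNA start to 80 nt into a 900-nt CDS
        cds = _cds(200, 1100)
        t = _t(150, 279)
        assert classify_srna(t, [cds]) == PUTATIVE_SRNA

    def test_five_utr_derived_shares_mrna_start(self):
        cds = _cds(200, 1100)
        mrna = _t(150, 1150)
        mrna.feature = CDS
        t = _t(150, 190)  # ends before the CDS start codon
        klass = classify_srna(t, [cds], cds_transcripts=[mrna])
        assert klass == FIVE_UTR_DERIVED

    def test_three_utr_derived_shares_mrna_stop(self):
        cds = _cds(200, 1100)
        mrna = _t(150, 1150)
        mrna.feature = CDS
        t = _t(1120, 1150)
        klass = classify_srna(t, [cds], cds_transcripts=[mrna])
        assert klass == THREE_UTR_DERIVED

    def test_intergenic_between_operonic_genes(self):
        operon = Operon(left=100, right=3000, strand="+", density=0.9)
        records = [_cds(100, 900), _cds(1500, 3000)]
        t = _t(950, 1400)
        assert classify_srna(t, records, operons=[operon]) == INTERGENIC

    def test_intragenic_inside_cds(self):
        operon = Operon(left=100, right=3000, strand="+", density=0.9)
        records = [_cds(100, 900)]
        t = _t(400, 700)
        # fully inside the CDS but not covering its start codon
        assert classify_srna(t, records, operons=[operon]) == INTRAGENIC

    def test_independent_split_by_isoform_partners(self):
        t = _t(5000, 5200)
        partner = _t(5000, 5400)
        assert classify_srna(t, [], partners=[partner]) == INDEPENDENT_WITH_ISOFORM
        assert classify_srna(t, []) == INDEPENDENT_WITHOUT_ISOFORM


class TestReadAnnotation:
    def test_gff3_parsing_with_names(self, tmp_path):
        path = tmp_path / "old.gff3"
        path.write_text(
            "##gff-version 3\n"
            "c\tsrc\tCDS\t100\t900\t.\t+\t0\tID=cds1;Name=abc\n"
            "c\tsrc\tsRNA\t2000\t2100\t.\t-\t.\tID=s1\n"
        )
        records = read_annotation(path)
        assert [(r.feature, r.left, r.right, r.strand) for r in records] == [
            ("CDS", 100, 900, "+"),
            ("sRNA", 2000, 2100, "-"),
        ]
        assert records[0].name == "abc"
        assert records[1].name == "s1"
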