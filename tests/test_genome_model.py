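"""Annotation model, file round trips, and dubious-overlap analysis."""

import pytest

from synchrom.design_rules import EditPlan, apply_edits
from synchrom.fixtures import FixtureSpec, make_mini_chromosome
from synchrom.genome_model import (
    AnnotationError,
    ChromosomeAnnotation,
    OrfFeature,
    find_dubious_overlaps,
    read_annotation,
    write_classification_table,
    write_design,
    write_genbank,
)

from conftest import plus_orf, toy_annotation


class TestOrfFeature:
    def test_dubious_cannot_be_essential(self):
        with pytest.raises(AnnotationError):
            OrfFeature(id="x", strand="+", exons=((0, 9),),
                       classification="dubious", essential=True)

    def test_unsorted_exons_rejected(self):
        with pytest.raises(AnnotationError):
            OrfFeature(id="x", strand="+", exons=((50, 60), (0, 9)))

    def test_spliced_cds_and_strand_geometry(self):
        #        0123456789012345
        seq = "ATGGCTTAGCCCCCCC"
        orf = plus_orf("f", 0, "ATGGCTTAG")
        assert orf.spliced_cds(seq) == "ATGGCTTAG"
        assert orf.loxpsym_insertion_point(3) == 12
        assert orf.upstream_window(5) == (-5, 0)
        # minus strand: genomic CTAAGCCAT reads ATGGCTTAG
        seq2 = "CCCCTAAGCCATCCCC"
        orf2 = OrfFeature(id="r", strand="-", exons=((3, 12),))
        assert orf2.spliced_cds(seq2) == "ATGGCTTAG"
        assert orf2.loxpsym_insertion_point(3) == 0
        assert orf2.upstream_window(5) == (12, 17)

    def test_cds_to_genomic_spliced_minus(self):
        orf = OrfFeature(id="s", strand="-", exons=((10, 16), (20, 26)))
        # first CDS base is the last base of the rightmost exon
        assert orf.cds_to_genomic(0) == 25
        assert orf.cds_to_genomic(5) == 20
        assert orf.cds_to_genomic(6) == 15
        assert orf.cds_to_genomic(11) == 10


class TestGenBankIO:
    def test_toy_two_genes_one_intron(self, tmp_path):
        seq = list("ACGT" * 50)
        seq[10:19] = "ATGGCTTAA"          # g1, single exon
        seq[50:59] = "ATGGCTGCT"          # g2 exon 1
        seq[70:76] = "GCTTAA"             # g2 exon 2
        ann = toy_annotation(
            "".join(seq),
            orfs=[
                plus_orf("g1", 10, "ATGGCTTAA"),
                OrfFeature(id="g2", strand="+", exons=((50, 59), (70, 76))),
            ],
        )
        path = tmp_path / "toy.gb"
        write_genbank(ann, path)
        back = read_annotation(path)
        assert len(back.orfs) == 2
        g2 = back.get_orf("g2")
        assert g2.exons == ((50, 59), (70, 76))

    def test_round_trip_preserves_fixture(self, tmp_path, mini):
        ann, _ = mini
        gb = tmp_path / "mini.gb"
        tsv = tmp_path / "mini.tsv"
        write_genbank(ann, gb)
        write_classification_table(ann, tsv)
        back = read_annotation(gb, tsv)
        assert back.sequence == ann.sequence
        assert [(o.id, o.strand, o.exons, o.classification, o.essential)
                for o in back.orfs] == \
               [(o.id, o.strand, o.exons, o.classification, o.essential)
                for o in ann.orfs]
        assert [(t.id, t.interval) for t in back.trnas] == \
               [(t.id, t.interval) for t in ann.trnas]
        assert back.centromere == ann.centromere

    def test_missing_classification_warns_and_defaults(self, tmp_path, mini):
        ann, _ = mini
        gb = tmp_path / "mini.gb"
        tsv = tmp_path / "partial.tsv"
        write_genbank(ann, gb)
        trimmed = ChromosomeAnnotation(
            name=ann.name, sequence=ann.sequence, orfs=ann.orfs[1:]
        )
        write_classification_table(trimmed, tsv)
        with pytest.warns(UserWarning, match=ann.orfs[0].id):
            back = read_annotation(gb, tsv)
        first = back.get_orf(ann.orfs[0].id)
        assert first.classification == "uncharacterized"
        assert not first.essential


class TestGff3:
    def test_one_based_conversion(self, tmp_path):
        fasta = tmp_path / "c.fa"
        fasta.write_text(">chr\n" + "ATGGCTTAA" + "C" * 91 + "\n")
        gff = tmp_path / "c.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr\tsrc\tCDS\t1\t9\t.\t+\t0\tID=g1\n"
        )
        ann = read_annotation(gff, fasta=fasta)
        assert ann.orfs[0].exons == ((0, 9),)

    def test_bad_coordinates_hard_error(self, tmp_path):
        fasta = tmp_path / "c.fa"
        fasta.write_text(">chr\nACGTACGTAC\n")
        gff = tmp_path / "c.gff3"
        gff.write_text("chr\tsrc\tCDS\t5\t999\t.\t+\t0\tID=bad\n")
        with pytest.raises(AnnotationError):
            read_annotation(gff, fasta=fasta)


class TestDubiousOverlaps:
    def test_engineered_pairs_reported_exactly_once(self, mini, v2_policy):
        ann, gt = mini
        records = find_dubious_overlaps(ann, v2_policy)
        assert len(records) == gt.overlap_records
        assert len({(r.dubious_id, r.verified_id) for r in records}) == len(records)
        for r in records:
            assert ann.get_orf(r.dubious_id).classification == "dubious"
            assert ann.get_orf(r.verified_id).classification == "verified"

    def test_no_dubious_means_empty(self, v2_policy):
        ann, _ = make_mini_chromosome(
            FixtureSpec(seed=5, length_bp=30_000, n_verified=5, n_dubious=0,
                        n_dubious_overlapping_verified=0,
                        n_dubious_stop_in_verified=0, n_tag_stop_codons=2,
                        n_uncharacterized=2, n_essential=1, n_intron=1,
                        n_enzyme_sites=1)
        )
        assert find_dubious_overlaps(ann, v2_policy) == []

    def test_antisense_proximal_flags_utr_intrusion(self, v2_policy):
        """A dubious ORF ending just past an antisense verified start puts its
        loxPsym point inside the verified upstream window."""
        ann, _ = make_mini_chromosome(
            FixtureSpec(seed=6, length_bp=30_000, n_verified=4,
                        n_uncharacterized=1, n_dubious=0,
                        n_dubious_overlapping_verified=1,
                        n_dubious_stop_in_verified=0, n_tag_stop_codons=2,
                        n_essential=1, n_intron=1, n_enzyme_sites=0,
                        tandem_repeat_cds=False)
        )
        records = find_dubious_overlaps(ann, v2_policy)
        assert len(records) == 1
        rec = records[0]
        assert rec.geometry == "antisense"
        assert rec.loxpsym_in_verified_5utr

    def test_nested_dubious_stop_hits_verified_cds(self, v2_policy):
        ann, _ = make_mini_chromosome(
            FixtureSpec(seed=7, length_bp=30_000, n_verified=4,
                        n_uncharacterized=1, n_dubious=0,
                        n_dubious_overlapping_verified=0,
                        n_dubious_stop_in_verified=1, n_tag_stop_codons=2,
                        n_essential=1, n_intron=1, n_enzyme_sites=0,
                        tandem_repeat_cds=False)
        )
        records = find_dubious_overlaps(ann, v2_policy)
        assert len(records) == 1
        assert records[0].stop_swap_hits_verified_cds

    def test_ten_locus_schematic(self, v2_policy):
        """Ten dubious ORFs overlapping verified 5' regions yield exactly ten
        window-intruding records."""
        ann, gt = make_mini_chromosome(
            FixtureSpec(seed=8, length_bp=90_000, n_verified=8,
                        n_dubious_overlapping_verified=10,
                        n_dubious_stop_in_verified=0, n_dubious=2)
        )
        records = find_dubious_overlaps(ann, v2_policy)
        assert sum(r.loxpsym_in_verified_5utr for r in records) == 10
        assert gt.overlap_records == 10


class TestWriteDesign:
    def test_empty_plan_fasta_equals_wild_type(self, tmp_path, mini):
        ann, _ = mini
        designed = apply_edits(ann, EditPlan())
        written = write_design(designed, None, tmp_path / "out")
        fasta = written["fasta"].read_text()
        assert "".join(fasta.splitlines()[1:]) == ann.sequence

    def test_chunk_files_match_segmentation(self, tmp_path, mini_v2):
        written = write_design(
            mini_v2.designed, mini_v2.segmentation, tmp_path / "out",
            tags=mini_v2.tags, audit_report=mini_v2.report,
        )
        per_chunk = [p for p in written["chunks"].parent.glob("*.fasta")
                     if p.name != "chunks.fasta"]
        assert len(per_chunk) == len(mini_v2.segmentation.chunks)

    def test_rereading_written_design_preserves_lifted_coords(self, tmp_path, mini_v2):
        written = write_design(mini_v2.designed, None, tmp_path / "out")
        back = read_annotation(written["genbank"])
        lifted = mini_v2.designed.features_lifted
        assert back.sequence == mini_v2.designed.sequence
        assert [(o.id, o.exons) for o in back.orfs] == \
               [(o.id, o.exons) for o in lifted.orfs]
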