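"""Taxonomy: codon classification, indel classes, region assignment, known/unknown."""

import itertools

import pytest
from Bio.Seq import Seq

from exomesift.classify import (
    GENETIC_CODE,
    GeneModel,
    assign_region,
    classify_indel,
    classify_snv,
    partition_known,
    validate_annotation,
)
from exomesift.datamodel import (
    FuncClass,
    Region,
    VariantType,
    normalize_variant,
)
from exomesift.errors import InvalidCodonPairError, OutOfCaptureError, WrongTypeError
from exomesift.io_formats import Catalogue

from conftest import make_annotation, make_variant


class TestClassifySnv:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("GCT", "GCC", FuncClass.SYNONYMOUS),  # Ala -> Ala
            ("TAC", "TAA", FuncClass.NONSENSE),    # Tyr -> stop
            ("TAA", "TAC", FuncClass.STOP_LOSS),
            ("GCT", "GTT", FuncClass.MISSENSE),    # Ala -> Val
            ("TAA", "TGA", FuncClass.SYNONYMOUS),  # stop -> stop
        ],
    )
    def test_examples(self, ref, alt, expected):
        assert classify_snv(ref, alt) is expected

    def test_multi_position_difference_rejected(self):
        with pytest.raises(InvalidCodonPairError):
            classify_snv("AAA", "TTT")
        with pytest.raises(InvalidCodonPairError):
            classify_snv("AAA", "AAA")
        with pytest.raises(InvalidCodonPairError):
            classify_snv("AAN", "AAA")

    def test_exhaustive_against_biopython_oracle(self):
        """All 576 single-position codon substitutions agree with an oracle
        built on an independent translation implementation."""
        n = 0
        for codon in GENETIC_CODE:
            for i in range(3):
                for base in "ACGT":
                    if base == codon[i]:
                        continue
                    alt = codon[:i] + base + codon[i + 1:]
                    aa_ref = str(Seq(codon).translate())
                    aa_alt = str(Seq(alt).translate())
                    if aa_ref == aa_alt:
                        expected = FuncClass.SYNONYMOUS
                    elif aa_alt == "*":
                        expected = FuncClass.NONSENSE
                    elif aa_ref == "*":
                        expected = FuncClass.STOP_LOSS
                    else:
                        expected = FuncClass.MISSENSE
                    assert classify_snv(codon, alt) is expected
                    n += 1
        assert n == 64 * 9


class TestClassifyIndel:
    def test_two_bp_deletion_is_frameshift(self):
        key = normalize_variant("1", 100, "ATT", "A")
        assert classify_indel(key, Region.CDS) is FuncClass.FRAMESHIFT

    def test_three_bp_insertion_preserves_frame(self):
        key = normalize_variant("1", 100, "A", "AGGG")
        assert classify_indel(key, Region.CDS) is FuncClass.NON_FRAMESHIFT

    def test_noncoding_indel_has_no_class(self):
        key = normalize_variant("1", 100, "ATTTT", "A")
        assert classify_indel(key, Region.UTR5) is FuncClass.NONE

    def test_snv_rejected(self):
        with pytest.raises(WrongTypeError):
            classify_indel(normalize_variant("1", 100, "A", "G"), Region.CDS)


@pytest.fixture()
def plus_gene():
    # 3 exons of 100 bp separated by 500-bp introns; 50-bp UTRs at each end
    return GeneModel(
        gene_id="G1", transcript="G1.t1", strand="+",
        exons=((1001, 1100), (1601, 1700), (2201, 2300)),
        cds_start=1051, cds_end=2250,
    )


class TestAssignRegion:
    def test_cds_and_utrs(self, plus_gene):
        assert assign_region(normalize_variant("1", 1060, "A", "G"), plus_gene) == (Region.CDS, 1)
        assert assign_region(normalize_variant("1", 1010, "A", "G"), plus_gene) == (Region.UTR5, 1)
        assert assign_region(normalize_variant("1", 2290, "A", "G"), plus_gene) == (Region.UTR3, 3)

    def test_splice_dinucleotide(self, plus_gene):
        # donor side of intron 2 (after exon 2)
        assert assign_region(normalize_variant("1", 1701, "A", "G"), plus_gene) == (Region.SPLICE_SITE, 2)
        # acceptor side of intron 1
        assert assign_region(normalize_variant("1", 1599, "A", "G"), plus_gene) == (Region.SPLICE_SITE, 1)

    def test_intron_flank_window(self, plus_gene):
        assert assign_region(normalize_variant("1", 1712, "A", "G"), plus_gene) == (Region.INTRON_FLANK, 2)
        assert assign_region(normalize_variant("1", 1120, "A", "G"), plus_gene) == (Region.INTRON_FLANK, 1)

    def test_deep_intron_rejected(self, plus_gene):
        with pytest.raises(OutOfCaptureError):
            assign_region(normalize_variant("1", 1725, "A", "G"), plus_gene)
        with pytest.raises(OutOfCaptureError):
            assign_region(normalize_variant("1", 500, "A", "G"), plus_gene)

    def test_reflection_with_strand_flip_preserves_labels(self, plus_gene):
        """Reflecting coordinates AND flipping the strand leaves every
        region label and exon/intron ordinal unchanged: the mirrored gene
        reads the same biology in the other direction."""
        mirror = 5000  # reflection: pos -> mirror - pos
        minus_gene = GeneModel(
            gene_id="G1", transcript="G1.t1", strand="-",
            exons=tuple(sorted((mirror - e, mirror - s) for s, e in plus_gene.exons)),
            cds_start=mirror - plus_gene.cds_end,
            cds_end=mirror - plus_gene.cds_start,
        )
        lo, hi = plus_gene.span
        for pos in range(lo, hi + 1):
            try:
                region, idx = assign_region(normalize_variant("1", pos, "A", "G"), plus_gene)
            except OutOfCaptureError:
                with pytest.raises(OutOfCaptureError):
                    assign_region(normalize_variant("1", mirror - pos, "A", "G"), minus_gene)
                continue
            m_region, m_idx = assign_region(
                normalize_variant("1", mirror - pos, "A", "G"), minus_gene
            )
            assert m_region is region
            assert m_idx == idx

    def test_strand_flip_alone_swaps_utrs(self, plus_gene):
        """Flipping only the strand of the same model exchanges UTR5 and
        UTR3 while CDS/splice/intron labels are unaffected."""
        flipped = GeneModel(
            gene_id="G1", transcript="G1.t1", strand="-",
            exons=plus_gene.exons,
            cds_start=plus_gene.cds_start, cds_end=plus_gene.cds_end,
        )
        swap = {Region.UTR5: Region.UTR3, Region.UTR3: Region.UTR5}
        lo, hi = plus_gene.span
        for pos in range(lo, hi + 1):
            try:
                region, _ = assign_region(normalize_variant("1", pos, "A", "G"), plus_gene)
            except OutOfCaptureError:
                continue
            f_region, _ = assign_region(normalize_variant("1", pos, "A", "G"), flipped)
            assert f_region is swap.get(region, region)


class TestPartitionKnown:
    def test_split_by_key(self):
        variants = [make_variant(pos=100 + i) for i in range(10)]
        cat = Catalogue("c", keys=frozenset(v.key for v in variants[:7]))
        known, unknown = partition_known(variants, cat)
        assert (len(known), len(unknown)) == (7, 3)

    def test_empty_catalogue_all_unknown(self):
        variants = [make_variant(pos=100 + i) for i in range(4)]
        known, unknown = partition_known(variants, Catalogue("empty"))
        assert known == [] and unknown == variants

    def test_rsid_only_match_under_either_policy(self):
        v = make_variant(rsid="rs77")
        cat = Catalogue("c", rsids=frozenset({"rs77"}), match="either")
        known, unknown = partition_known([v], cat)
        assert known == [v] and unknown == []

    def test_no_loss_no_duplication(self, project, catalogues):
        cat = next(iter(catalogues.values()))
        known, unknown = partition_known(project.variants, cat)
        assert len(known) + len(unknown) == len(project.variants)
        recombined = sorted(known + unknown, key=id)
        assert sorted(project.variants, key=id) == recombined


class TestValidateAnnotation:
    def test_concordant_annotation_passes(self):
        key = normalize_variant("1", 100, "A", "G")
        ann = make_annotation(func_class=FuncClass.MISSENSE, codon_ref="GCT", codon_alt="GTT")
        assert validate_annotation(key, ann) == []

    def test_discordant_class_reported_but_not_overwritten(self):
        key = normalize_variant("1", 100, "A", "G")
        ann = make_annotation(func_class=FuncClass.NONSENSE, codon_ref="GCT", codon_alt="GTT")
        issues = validate_annotation(key, ann)
        assert issues and "NONSENSE" in issues[0]
        assert ann.func_class is FuncClass.NONSENSE  # file value wins

    def test_indel_with_snv_class_reported(self):
        key = normalize_variant("1", 100, "AT", "A")
        ann = make_annotation(func_class=FuncClass.MISSENSE)
        assert validate_annotation(key, ann)
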