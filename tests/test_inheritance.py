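"""Inheritance strategies: recurrence binning, family sharing, de novo trios."""

import itertools

import pytest

from exomesift.datamodel import FuncClass, Zygosity
from exomesift.errors import ConfigError
from exomesift.inheritance import (
    compound_heterozygous,
    de_novo,
    recurrence,
    shared_family,
)

from conftest import make_annotation, make_variant


def gene_variant(gene, pos, individual, zygosity=Zygosity.HET):
    return make_variant(
        pos=pos, individual=individual, zygosity=zygosity,
        annotations=[make_annotation(gene=gene)],
    )


class TestRecurrence:
    def test_exact_level_binning(self):
        variants = [
            gene_variant("G", 100, "I1"),
            gene_variant("G", 101, "I2"),
            gene_variant("H", 200, "I3"),
        ]
        table = recurrence(variants, ["I1", "I2", "I3"])
        assert table.genes_at(2) == ["G"]
        assert table.genes_at(1) == ["H"]
        assert table.genes_at(3) == []
        assert table.count(2) == 1 and table.count(1) == 1

    def test_no_variants_all_levels_empty(self):
        table = recurrence([], ["I1", "I2"])
        assert table.total_genes == 0

    def test_empty_selection_rejected(self):
        with pytest.raises(ConfigError):
            recurrence([gene_variant("G", 100, "I1")], [])

    def test_partition_property(self, sim_cohort):
        """Levels are disjoint and counts sum to the distinct genes hit."""
        from exomesift.filters import primary_screen

        project, catalogues = sim_cohort["project"], sim_cohort["catalogues"]
        hits = primary_screen(project, catalogues)
        inds = [i.individual_id for i in project.individuals]
        table = recurrence(hits, inds)
        all_genes = [g for k in table.levels for g in table.levels[k]]
        assert len(all_genes) == len(set(all_genes))
        expected = {a.gene_id for v in hits for a in v.annotations}
        assert set(all_genes) == expected

    def test_permutation_invariance(self):
        variants = [gene_variant("G", 100, "I1"), gene_variant("G", 101, "I3"),
                    gene_variant("H", 200, "I2")]
        t1 = recurrence(variants, ["I1", "I2", "I3"])
        t2 = recurrence(variants, ["I3", "I1", "I2"])
        assert t1.levels == t2.levels

    def test_planted_gene_lands_at_its_carrier_count(self, sim_cohort):
        from exomesift.filters import primary_screen

        project, catalogues = sim_cohort["project"], sim_cohort["catalogues"]
        hits = primary_screen(project, catalogues)
        inds = [i.individual_id for i in project.individuals]
        table = recurrence(hits, inds)
        assert table.level_of("G0003") == 3

    def test_recessive_mode_requires_hom_or_two_hets(self):
        variants = [
            gene_variant("G", 100, "I1", Zygosity.HOM),           # carrier
            gene_variant("H", 200, "I1", Zygosity.HET),           # single het: no
            gene_variant("K", 300, "I1", Zygosity.HET),
            gene_variant("K", 301, "I1", Zygosity.HET),           # compound het: yes
        ]
        table = recurrence(variants, ["I1"], zygosity_mode="recessive")
        assert set(table.genes_at(1)) == {"G", "K"}


class TestSharedFamily:
    def test_hom_shared_by_both_sibs(self):
        variants = [
            gene_variant("G", 100, "SIB1", Zygosity.HOM),
            gene_variant("G", 100, "SIB2", Zygosity.HOM),
        ]
        shared = shared_family(variants, ["SIB1", "SIB2"], "HOM")
        assert list(shared) == ["G"]
        assert len(shared["G"]) == 1

    def test_variant_in_one_sib_only_excluded(self):
        variants = [gene_variant("G", 100, "SIB1")]
        assert shared_family(variants, ["SIB1", "SIB2"], "EITHER") == {}

    def test_zygosity_mode_filters_mismatched_genotypes(self):
        variants = [
            gene_variant("G", 100, "SIB1", Zygosity.HOM),
            gene_variant("G", 100, "SIB2", Zygosity.HET),
        ]
        assert shared_family(variants, ["SIB1", "SIB2"], "HOM") == {}
        assert list(shared_family(variants, ["SIB1", "SIB2"], "EITHER")) == ["G"]

    def test_planted_shared_keys_recovered_exactly(self):
        variants = []
        for pos in range(100, 150):  # background: SIB1-private variants
            variants.append(gene_variant("BG", pos, "SIB1"))
        planted = []
        for pos in range(500, 505):  # 5 planted shared-HOM keys
            planted.append(pos)
            for sib in ("SIB1", "SIB2"):
                variants.append(gene_variant("CAND", pos, sib, Zygosity.HOM))
        shared = shared_family(variants, ["SIB1", "SIB2"], "HOM")
        assert [k.pos for k in shared["CAND"]] == planted
        assert list(shared) == ["CAND"]

    def test_fewer_than_two_individuals_rejected(self):
        with pytest.raises(ConfigError):
            shared_family([], ["SIB1"], "HOM")


class TestCompoundHeterozygous:
    def test_two_het_keys_reported(self):
        variants = [gene_variant("G", 100, "I1"), gene_variant("G", 200, "I1")]
        result = compound_heterozygous(variants, "I1")
        assert [k.pos for k in result["G"]] == [100, 200]

    def test_single_het_not_reported(self):
        assert compound_heterozygous([gene_variant("G", 100, "I1")], "I1") == {}

    def test_hom_keys_do_not_count(self):
        variants = [gene_variant("G", 100, "I1", Zygosity.HOM),
                    gene_variant("G", 200, "I1")]
        assert compound_heterozygous(variants, "I1") == {}

    def test_cis_configuration_removed_with_parents(self):
        child = [gene_variant("G", 100, "C"), gene_variant("G", 200, "C")]
        mother = [gene_variant("G", 100, "M"), gene_variant("G", 200, "M")]
        father = []
        assert compound_heterozygous(child, "C", father, mother) == {}
        # one key per parent: compatible with trans, kept
        father2 = [gene_variant("G", 200, "F")]
        mother2 = [gene_variant("G", 100, "M")]
        assert "G" in compound_heterozygous(child, "C", father2, mother2)


class TestDeNovo:
    def test_retained_and_removed(self):
        child = [gene_variant("G", 100, "C")]
        assert de_novo(child, [], []) == child
        mother = [gene_variant("G", 100, "M")]
        assert de_novo(child, [], mother) == []

    def test_missing_parent_collection_rejected(self):
        with pytest.raises(ConfigError):
            de_novo([gene_variant("G", 100, "C")], None, [])

    def test_symmetric_in_parents(self):
        child = [gene_variant("G", 100, "C"), gene_variant("H", 200, "C")]
        father = [gene_variant("G", 100, "F")]
        mother = [gene_variant("H", 200, "M")]
        assert de_novo(child, father, mother) == de_novo(child, mother, father)

    def test_truth_table_over_all_27_genotype_combinations(self):
        """Explicit enumeration: over {absent, HET, HOM}^3 for
        (child, father, mother), a key is retained iff the child carries it
        and neither parent does — the 2 such combinations of 27."""
        states = [None, Zygosity.HET, Zygosity.HOM]
        retained = 0
        for child_s, father_s, mother_s in itertools.product(states, repeat=3):
            child = [gene_variant("G", 100, "C", child_s)] if child_s else []
            father = [gene_variant("G", 100, "F", father_s)] if father_s else []
            mother = [gene_variant("G", 100, "M", mother_s)] if mother_s else []
            result = de_novo(child, father, mother)
            expected = child_s is not None and father_s is None and mother_s is None
            assert (len(result) == 1) == expected
            retained += bool(result)
        assert retained == 2

    def test_simulated_trio_recovers_only_planted_keys(self, sim_cohort):
        project = sim_cohort["project"]
        truth = sim_cohort["sim"].truth
        result = de_novo(
            project.variants_of("IND06"),
            project.variants_of("IND07"),
            project.variants_of("IND08"),
        )
        planted_keys = {
            key for plant in truth["planted"] if plant["gene"] == "G0004"
            for key in plant["keys"].values()
        }
        assert {str(v.key) for v in result} == planted_keys
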