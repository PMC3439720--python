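"""Recipe engine: conjunction semantics, primary screen, overview table."""

import numpy as np
import pytest

from exomesift.datamodel import FuncClass, Project, Region, Zygosity
from exomesift.errors import ConfigError
from exomesift.filters import (
    FilterRecipe,
    apply_recipe,
    overview,
    primary_screen,
)
from exomesift.io_formats import Catalogue

from _oracle import brute_force_filter, random_recipe, strengthen
from conftest import make_annotation, make_individual, make_variant


@pytest.fixture()
def six_variant_project():
    variants = [
        make_variant(pos=100, quality=50),
        make_variant(pos=110, quality=30),
        make_variant(pos=120, quality=12),
        make_variant(pos=130, quality=11),
        make_variant(pos=140, quality=8),
        make_variant(pos=150, quality=2),
    ]
    return Project("six", individuals=[make_individual("IND01")], variants=variants)


class TestApplyRecipe:
    def test_quality_threshold(self, six_variant_project):
        hits = apply_recipe(six_variant_project, FilterRecipe(min_quality=10.5))
        assert len(hits) == 4  # the four variants above the phred-10 threshold

    def test_empty_recipe_returns_everything(self, six_variant_project):
        hits = apply_recipe(six_variant_project, FilterRecipe())
        assert len(hits) == len(six_variant_project.variants)

    def test_excluding_a_complete_catalogue_empties_the_result(self, six_variant_project):
        cat = Catalogue("all", keys=frozenset(v.key for v in six_variant_project.variants))
        hits = apply_recipe(
            six_variant_project, FilterRecipe(exclude_catalogues=("all",)), {"all": cat}
        )
        assert hits == []

    def test_unknown_catalogue_and_individual_are_config_errors(self, six_variant_project):
        with pytest.raises(ConfigError):
            apply_recipe(six_variant_project, FilterRecipe(exclude_catalogues=("nope",)))
        with pytest.raises(ConfigError):
            apply_recipe(six_variant_project, FilterRecipe(individuals=frozenset({"GHOST"})))

    def test_region_and_class_must_hold_on_the_same_annotation(self):
        # one transcript is a synonymous CDS hit, the other a splice hit;
        # asking for missense CDS must not be satisfied by mixing them
        v = make_variant(annotations=[
            make_annotation(region=Region.CDS, func_class=FuncClass.SYNONYMOUS),
            make_annotation(transcript="G1.t2", region=Region.SPLICE_SITE,
                            func_class=FuncClass.NONE),
        ])
        proj = Project("p", individuals=[make_individual("IND01")], variants=[v])
        recipe = FilterRecipe(
            include_regions=frozenset({Region.CDS}),
            include_func_classes=frozenset({FuncClass.NONE}),
        )
        assert apply_recipe(proj, recipe) == []

    def test_any_versus_all_annotation_matching(self):
        v = make_variant(annotations=[
            make_annotation(func_class=FuncClass.MISSENSE),
            make_annotation(transcript="G1.t2", func_class=FuncClass.SYNONYMOUS),
        ])
        proj = Project("p", individuals=[make_individual("IND01")], variants=[v])
        wanting_missense = {"include_func_classes": frozenset({FuncClass.MISSENSE})}
        assert apply_recipe(proj, FilterRecipe(**wanting_missense)) == [v]
        assert apply_recipe(proj, FilterRecipe(**wanting_missense, annotation_match="all")) == []

    def test_serialization_round_trip(self):
        recipe = FilterRecipe(
            exclude_catalogues=("dbsnp-like", "hapmap-like"),
            include_func_classes=frozenset({FuncClass.MISSENSE, FuncClass.FRAMESHIFT}),
            include_regions=frozenset({Region.CDS, Region.SPLICE_SITE}),
            genomic_interval=("7", 1, 10_000),
            genes=frozenset({"G1"}),
            zygosity=Zygosity.HET,
            min_quality=10.0,
            min_coverage=8,
            individuals=frozenset({"IND01"}),
        )
        assert FilterRecipe.from_yaml(recipe.to_yaml()) == recipe
        assert FilterRecipe.from_json(recipe.to_json()) == recipe


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_recipes(self, project, catalogues):
        """The recipe engine equals an independent per-variant boolean check."""
        rng = np.random.default_rng(2024)
        genes = sorted({a.gene_id for v in project.variants for a in v.annotations})
        inds = [i.individual_id for i in project.individuals]
        for _ in range(50):
            recipe = random_recipe(rng, genes, inds, sorted(catalogues))
            assert apply_recipe(project, recipe, catalogues) == brute_force_filter(
                project.variants, recipe, catalogues
            )

    def test_adding_a_constraint_never_grows_the_result(self, project, catalogues):
        rng = np.random.default_rng(7)
        genes = sorted({a.gene_id for v in project.variants for a in v.annotations})
        inds = [i.individual_id for i in project.individuals]
        checked = 0
        while checked < 100:
            recipe = random_recipe(rng, genes, inds, sorted(catalogues))
            stronger = strengthen(rng, recipe, genes, inds, sorted(catalogues))
            if stronger is None:
                continue
            n0 = len(apply_recipe(project, recipe, catalogues))
            n1 = len(apply_recipe(project, stronger, catalogues))
            assert n1 <= n0
            checked += 1


class TestPrimaryScreen:
    def test_planted_variants_survive(self, sim_cohort):
        project, catalogues = sim_cohort["project"], sim_cohort["catalogues"]
        hits = primary_screen(project, catalogues)
        hit_set = {(v.key, v.individual_id) for v in hits}
        for plant in sim_cohort["sim"].truth["planted"]:
            for carrier, key_str in plant["keys"].items():
                chrom, pos, change = key_str.split(":")
                ref, alt = change.split(">")
                match = [k for k, ind in hit_set
                         if ind == carrier and str(k) == key_str]
                assert match, f"planted {key_str} of {carrier} lost by the screen"

    def test_every_hit_is_unknown_het_deleterious_or_splice(self, sim_cohort):
        project, catalogues = sim_cohort["project"], sim_cohort["catalogues"]
        for v in primary_screen(project, catalogues):
            assert v.zygosity is Zygosity.HET
            assert not any(c.contains(v.key, v.rsid) for c in catalogues.values())
            assert any(
                (a.region is Region.CDS and a.func_class in
                 {FuncClass.MISSENSE, FuncClass.NONSENSE, FuncClass.STOP_LOSS,
                  FuncClass.FRAMESHIFT})
                or a.region is Region.SPLICE_SITE
                for a in v.annotations
            )

    def test_all_synonymous_cohort_screens_to_nothing(self):
        variants = [
            make_variant(pos=100 + i,
                         annotations=[make_annotation(func_class=FuncClass.SYNONYMOUS)])
            for i in range(5)
        ]
        proj = Project("syn", individuals=[make_individual("IND01")], variants=variants)
        assert primary_screen(proj, {"c": Catalogue("c")}) == []

    def test_hom_only_cohort_screens_to_nothing(self):
        variants = [make_variant(pos=100 + i, zygosity=Zygosity.HOM) for i in range(5)]
        proj = Project("hom", individuals=[make_individual("IND01")], variants=variants)
        assert primary_screen(proj, {"c": Catalogue("c")}) == []


class TestOverview:
    def test_direct_tally(self):
        cat_keys = []
        variants = []
        for i in range(3):  # three known synonymous
            v = make_variant(pos=100 + i,
                             annotations=[make_annotation(func_class=FuncClass.SYNONYMOUS)])
            variants.append(v)
            cat_keys.append(v.key)
        variants.append(make_variant(pos=200,
                                     annotations=[make_annotation(func_class=FuncClass.NONSENSE)]))
        proj = Project("p", individuals=[make_individual("IND01")], variants=variants)
        table = overview(proj, Catalogue("c", keys=frozenset(cat_keys)))
        assert table.cell("IND01", "known", "synonymous") == 3
        assert table.cell("IND01", "unknown", "nonsense") == 1
        assert table.individual_total("IND01") == 4

    def test_empty_project(self):
        table = overview(Project("empty"), Catalogue("c"))
        assert len(table.rows) == 0

    def test_conservation_against_simulator_truth(self, sim_cohort):
        """Sum of an individual's cells equals the count of displayable
        variants the generator recorded (coding CDS classes + splice +/-2)."""
        project, catalogues = sim_cohort["project"], sim_cohort["catalogues"]
        table = overview(project, catalogues["known"])
        truth = sim_cohort["sim"].truth
        displayable = {"SYNONYMOUS", "MISSENSE", "STOP_LOSS", "NONSENSE",
                       "FRAMESHIFT", "NON_FRAMESHIFT"}
        for individual, rec in truth["individuals"].items():
            expected = sum(
                1 for t in rec["variants"]
                if t["func_class"] in displayable or t["region"] == "SPLICE_SITE"
            )
            assert table.individual_total(individual) == expected
            n_known = sum(
                1 for t in rec["variants"]
                if (t["func_class"] in displayable or t["region"] == "SPLICE_SITE")
                and t["known"]
            )
            known_cells = table.rows[
                (table.rows["individual_id"] == individual)
                & (table.rows["status"] == "known")
            ]
            assert int(known_cells.iloc[0, 2:].sum()) == n_known
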