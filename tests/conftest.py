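import pytest

from exomesift.cohortsim import Plant, SimConfig, simulate
from exomesift.datamodel import (
    FuncClass,
    FunctionalAnnotation,
    Individual,
    ObservedVariant,
    Region,
    Role,
    Zygosity,
    normalize_variant,
)
from exomesift.io_formats import load_project


def make_annotation(
    gene="G1",
    transcript=None,
    region=Region.CDS,
    func_class=FuncClass.MISSENSE,
    **kwargs,
):
    return FunctionalAnnotation(
        gene_id=gene,
        gene_symbol=gene,
        transcript=transcript or f"{gene}.t1",
        region=region,
        func_class=func_class,
        **kwargs,
    )


def make_variant(
    chrom="1",
    pos=100,
    ref="A",
    alt="G",
    individual="IND01",
    zygosity=Zygosity.HET,
    quality=50.0,
    coverage=40,
    rsid=None,
    annotations=None,
):
    if annotations is None:
        annotations = (make_annotation(),)
    return ObservedVariant(
        key=normalize_variant(chrom, pos, ref, alt),
        individual_id=individual,
        zygosity=zygosity,
        quality=quality,
        coverage=coverage,
        rsid=rsid,
        annotations=tuple(annotations),
    )


def make_individual(individual_id, family=None, role=Role.INDEX, affected=True):
    return Individual(individual_id, family, role, affected)


@pytest.fixture(scope="session")
def sim_cohort(tmp_path_factory):
    """Small simulated cohort: 5 unrelated cases + 1 trio, 2 plants.

    G0003 is planted as distinct unknown HET missense variants in 3
    unrelated individuals; G0004 is planted de novo in the trio child
    IND06 (parents IND07/IND08).
    """
    cfg = SimConfig(
        seed=11,
        n_individuals=8,
        n_genes=40,
        variants_per_individual=80,
        known_fraction=0.9,
        planted=(
            Plant(gene="G0003", carriers=("IND01", "IND02", "IND03")),
            Plant(gene="G0004", carriers=("IND06",)),
        ),
        trios=(("IND06", "IND07", "IND08"),),
        name="conftest-cohort",
    )
    outdir = tmp_path_factory.mktemp("sim_cohort")
    sim = simulate(cfg, outdir)
    project, catalogues = load_project(sim.manifest_path)
    return {"config": cfg, "sim": sim, "project": project, "catalogues": catalogues}


@pytest.fixture()
def project(sim_cohort):
    return sim_cohort["project"]


@pytest.fixture()
def catalogues(sim_cohort):
    return sim_cohort["catalogues"]
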