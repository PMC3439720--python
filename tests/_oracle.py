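"""Independent brute-force filter oracle and random-recipe generator.

Deliberately written as a flat per-variant boolean walk sharing no code
with exomesift.filters, so it can serve as an independent check of the
recipe engine.
"""

from __future__ import annotations

from exomesift.datamodel import CHROMOSOMES, FuncClass, Region, Zygosity
from exomesift.filters import FilterRecipe

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


def brute_force_filter(variants, recipe, catalogues):
    """Direct re-statement of recipe semantics, one plain check per variant."""
    kept = []
    for v in variants:
        if recipe.individuals:
            if v.individual_id not in recipe.individuals:
                continue
        if recipe.zygosity is not None:
            if v.zygosity != recipe.zygosity:
                continue
        if recipe.min_quality is not None:
            if v.quality < recipe.min_quality:
                continue
        if recipe.min_coverage is not None:
            if v.coverage < recipe.min_coverage:
                continue
        if recipe.genomic_interval is not None:
            chrom, start, end = recipe.genomic_interval
            if v.key.chrom != chrom:
                continue
            if v.key.pos < start or v.key.pos > end:
                continue
        found_in_catalogue = False
        for name in recipe.exclude_catalogues:
            cat = catalogues[name]
            in_by_key = v.key in cat.keys
            in_by_rsid = v.rsid is not None and v.rsid in cat.rsids
            if cat.match == "key" and in_by_key:
                found_in_catalogue = True
            elif cat.match == "rsid" and in_by_rsid:
                found_in_catalogue = True
            elif cat.match == "either" and (in_by_key or in_by_rsid):
                found_in_catalogue = True
        if found_in_catalogue:
            continue
        if recipe.genes:
            gene_hit = False
            for ann in v.annotations:
                if ann.gene_id in recipe.genes:
                    gene_hit = True
            if not gene_hit:
                continue
        if recipe.include_regions or recipe.include_func_classes:
            verdicts = []
            for ann in v.annotations:
                ok = True
                if recipe.include_regions and ann.region not in recipe.include_regions:
                    ok = False
                if (
                    recipe.include_func_classes
                    and ann.func_class not in recipe.include_func_classes
                ):
                    ok = False
                verdicts.append(ok)
            if recipe.annotation_match == "any":
                if True not in verdicts:
                    continue
            else:
                if not verdicts or False in verdicts:
                    continue
        kept.append(v)
    kept.sort(
        key=lambda v: (
            _CHROM_RANK[v.key.chrom],
            v.key.pos,
            v.key.ref,
            v.key.alt,
            v.individual_id,
        )
    )
    return kept


def random_recipe(rng, gene_ids, individual_ids, catalogue_names):
    """Random FilterRecipe over the cohort's vocabulary (seeded rng)."""
    kwargs = {}
    if rng.random() < 0.5 and catalogue_names:
        kwargs["exclude_catalogues"] = tuple(
            sorted(rng.choice(catalogue_names, size=1))
        )
    if rng.random() < 0.5:
        n = int(rng.integers(1, len(FuncClass)))
        kwargs["include_func_classes"] = frozenset(
            FuncClass(c) for c in rng.choice([c.value for c in FuncClass], size=n, replace=False)
        )
    if rng.random() < 0.5:
        n = int(rng.integers(1, len(Region)))
        kwargs["include_regions"] = frozenset(
            Region(r) for r in rng.choice([r.value for r in Region], size=n, replace=False)
        )
    if rng.random() < 0.3 and gene_ids:
        n = int(rng.integers(1, min(6, len(gene_ids) + 1)))
        kwargs["genes"] = frozenset(rng.choice(gene_ids, size=n, replace=False))
    if rng.random() < 0.4:
        kwargs["zygosity"] = Zygosity.HET if rng.random() < 0.7 else Zygosity.HOM
    if rng.random() < 0.4:
        kwargs["min_quality"] = float(rng.uniform(10, 55))
    if rng.random() < 0.3:
        kwargs["min_coverage"] = int(rng.integers(30, 90))
    if rng.random() < 0.3 and individual_ids:
        n = int(rng.integers(1, len(individual_ids) + 1))
        kwargs["individuals"] = frozenset(rng.choice(individual_ids, size=n, replace=False))
    if rng.random() < 0.2:
        chrom = str(rng.choice([c for c in CHROMOSOMES[:5]]))
        start = int(rng.integers(1, 40_000))
        kwargs["genomic_interval"] = (chrom, start, start + int(rng.integers(1_000, 60_000)))
    if rng.random() < 0.2:
        kwargs["annotation_match"] = "all"
    return FilterRecipe(**kwargs)


def strengthen(rng, recipe, gene_ids, individual_ids, catalogue_names):
    """Add one constraint to a recipe (returns None when nothing addable)."""
    options = []
    if recipe.min_quality is None:
        options.append(lambda: {"min_quality": float(rng.uniform(10, 55))})
    else:
        options.append(lambda: {"min_quality": recipe.min_quality + float(rng.uniform(1, 10))})
    if recipe.min_coverage is None:
        options.append(lambda: {"min_coverage": int(rng.integers(30, 90))})
    if recipe.zygosity is None:
        options.append(lambda: {"zygosity": Zygosity.HET if rng.random() < 0.5 else Zygosity.HOM})
    if not recipe.exclude_catalogues and catalogue_names:
        options.append(lambda: {"exclude_catalogues": tuple(catalogue_names[:1])})
    if not recipe.include_regions:
        options.append(lambda: {"include_regions": frozenset({Region.CDS, Region.SPLICE_SITE})})
    elif len(recipe.include_regions) > 1:
        options.append(lambda: {"include_regions": frozenset(sorted(recipe.include_regions)[:-1])})
    if not recipe.include_func_classes:
        options.append(
            lambda: {"include_func_classes": frozenset({FuncClass.MISSENSE, FuncClass.SYNONYMOUS})}
        )
    elif len(recipe.include_func_classes) > 1:
        options.append(
            lambda: {"include_func_classes": frozenset(sorted(recipe.include_func_classes)[:-1])}
        )
    if not recipe.individuals and individual_ids:
        n = max(1, len(individual_ids) // 2)
        options.append(
            lambda: {"individuals": frozenset(rng.choice(individual_ids, size=n, replace=False))}
        )
    if not options:
        return None
    pick = options[int(rng.integers(0, len(options)))]
    d = {f: getattr(recipe, f) for f in (
        "exclude_catalogues", "include_func_classes", "include_regions",
        "genomic_interval", "genes", "zygosity", "min_quality", "min_coverage",
        "individuals", "annotation_match",
    )}
    d.update(pick())
    return FilterRecipe(**d)
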