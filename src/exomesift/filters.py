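"""Declarative variant filters and the variation-overview table.

A :class:`FilterRecipe` is a conjunction of optional criteria (catalogue
exclusion, functional class, genic/genomic region, zygosity, quality,
coverage, gene and individual selections); empty fields mean "no
constraint".  Region and class constraints are evaluated per annotation
jointly — a variant passes when at least one of its transcript annotations
satisfies both — which matches a screening tool's any-transcript
sensitivity while keeping class and region coherent on the same transcript.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .datamodel import (
    FuncClass,
    ObservedVariant,
    Project,
    Region,
    Zygosity,
    chrom_sort_key,
    normalize_chrom,
    variant_sort_key,
)
from .errors import ConfigError
from .io_formats import Catalogue

__all__ = [
    "FilterRecipe",
    "DELETERIOUS_CLASSES",
    "apply_recipe",
    "primary_screen",
    "primary_screen_recipe",
    "OverviewTable",
    "overview",
]

#: SNV/indel classes treated as presumed deleterious in the primary screen.
DELETERIOUS_CLASSES = frozenset(
    {FuncClass.MISSENSE, FuncClass.NONSENSE, FuncClass.STOP_LOSS, FuncClass.FRAMESHIFT}
)


@dataclass(frozen=True)
class FilterRecipe:
    """Conjunction of filter criteria; ``None``/empty fields are inactive.

    Serializable to/from YAML and JSON without loss (:meth:`to_dict`,
    :meth:`from_dict`).  ``annotation_match`` selects whether one
    qualifying transcript annotation suffices (``any``, the default) or all
    must qualify (``all``).
    """

    exclude_catalogues: tuple[str, ...] = ()
    include_func_classes: frozenset[FuncClass] = frozenset()
    include_regions: frozenset[Region] = frozenset()
    genomic_interval: Optional[tuple[str, int, int]] = None
    genes: frozenset[str] = frozenset()
    zygosity: Optional[Zygosity] = None
    min_quality: Optional[float] = None
    min_coverage: Optional[int] = None
    individuals: frozenset[str] = frozenset()
    annotation_match: str = "any"

    def __post_init__(self) -> None:
        if self.annotation_match not in {"any", "all"}:
            raise ConfigError(
                f"annotation_match must be 'any' or 'all', got {self.annotation_match!r}"
            )

    def to_dict(self) -> dict:
        d: dict = {}
        if self.exclude_catalogues:
            d["exclude_catalogues"] = sorted(self.exclude_catalogues)
        if self.include_func_classes:
            d["include_func_classes"] = sorted(c.value for c in self.include_func_classes)
        if self.include_regions:
            d["include_regions"] = sorted(r.value for r in self.include_regions)
        if self.genomic_interval:
            c, s, e = self.genomic_interval
            d["genomic_interval"] = {"chrom": c, "start": s, "end": e}
        if self.genes:
            d["genes"] = sorted(self.genes)
        if self.zygosity:
            d["zygosity"] = self.zygosity.value
        if self.min_quality is not None:
            d["min_quality"] = self.min_quality
        if self.min_coverage is not None:
            d["min_coverage"] = self.min_coverage
        if self.individuals:
            d["individuals"] = sorted(self.individuals)
        if self.annotation_match != "any":
            d["annotation_match"] = self.annotation_match
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterRecipe":
        gi = d.get("genomic_interval")
        interval = None
        if gi:
            interval = (normalize_chrom(gi["chrom"]), int(gi["start"]), int(gi["end"]))
        return cls(
            exclude_catalogues=tuple(d.get("exclude_catalogues", ())),
            include_func_classes=frozenset(
                FuncClass(c) for c in d.get("include_func_classes", ())
            ),
            include_regions=frozenset(Region(r) for r in d.get("include_regions", ())),
            genomic_interval=interval,
            genes=frozenset(d.get("genes", ())),
            zygosity=Zygosity(d["zygosity"]) if d.get("zygosity") else None,
            min_quality=float(d["min_quality"]) if d.get("min_quality") is not None else None,
            min_coverage=int(d["min_coverage"]) if d.get("min_coverage") is not None else None,
            individuals=frozenset(d.get("individuals", ())),
            annotation_match=d.get("annotation_match", "any"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "FilterRecipe":
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FilterRecipe":
        return cls.from_dict(json.loads(text))


def _annotation_qualifies(ann, recipe: FilterRecipe) -> bool:
    if recipe.include_regions and ann.region not in recipe.include_regions:
        return False
    if recipe.include_func_classes and ann.func_class not in recipe.include_func_classes:
        return False
    return True


def _variant_passes(
    v: ObservedVariant, recipe: FilterRecipe, catalogues: Mapping[str, Catalogue]
) -> bool:
    if recipe.individuals and v.individual_id not in recipe.individuals:
        return False
    if recipe.zygosity is not None and v.zygosity is not recipe.zygosity:
        return False
    if recipe.min_quality is not None and v.quality < recipe.min_quality:
        return False
    if recipe.min_coverage is not None and v.coverage < recipe.min_coverage:
        return False
    if recipe.genomic_interval is not None:
        c, s, e = recipe.genomic_interval
        if v.key.chrom != c or not (s <= v.key.pos <= e):
            return False
    for name in recipe.exclude_catalogues:
        if catalogues[name].contains(v.key, v.rsid):
            return False
    if recipe.genes and not any(a.gene_id in recipe.genes for a in v.annotations):
        return False
    if recipe.include_regions or recipe.include_func_classes:
        if not v.annotations:
            return False
        hits = [_annotation_qualifies(a, recipe) for a in v.annotations]
        if recipe.annotation_match == "any":
            if not any(hits):
                return False
        elif not all(hits):
            return False
    return True


def apply_recipe(
    project: Project,
    recipe: FilterRecipe,
    catalogues: Optional[Mapping[str, Catalogue]] = None,
) -> list[ObservedVariant]:
    """All project variants satisfying every active recipe constraint.

    Output order is deterministic: (chrom, pos, alleles, individual).  An
    empty recipe returns all variants.
    """
    catalogues = catalogues or {}
    for name in recipe.exclude_catalogues:
        if name not in catalogues:
            raise ConfigError(f"recipe names unknown catalogue {name!r}")
    known_ids = {i.individual_id for i in project.individuals}
    unknown = recipe.individuals - known_ids
    if unknown:
        raise ConfigError(f"recipe names unknown individual(s) {sorted(unknown)}")
    hits = [v for v in project.variants if _variant_passes(v, recipe, catalogues)]
    return sorted(hits, key=variant_sort_key)


def primary_screen_recipe(catalogue_names: Sequence[str]) -> FilterRecipe:
    """The stringent primary-screen recipe as a reusable FilterRecipe.

    Keeps heterozygous variants absent from every listed catalogue whose
    molecular type is presumed deleterious: non-synonymous coding SNVs,
    frameshift coding indels, and splice donor/acceptor variants.  NONE is
    included in the class set solely so splice-site annotations (which carry
    no coding class) survive the joint region+class check; coding
    annotations always carry a real class.
    """
    return FilterRecipe(
        exclude_catalogues=tuple(catalogue_names),
        include_func_classes=frozenset(DELETERIOUS_CLASSES | {FuncClass.NONE}),
        include_regions=frozenset({Region.CDS, Region.SPLICE_SITE}),
        zygosity=Zygosity.HET,
    )


def primary_screen(
    project: Project, catalogues: Mapping[str, Catalogue]
) -> list[ObservedVariant]:
    """Apply the primary screen against every supplied catalogue."""
    return apply_recipe(project, primary_screen_recipe(sorted(catalogues)), catalogues)


# ---------------------------------------------------------------------------
# variation overview


_OVERVIEW_COLUMNS = [
    "synonymous",
    "missense",
    "stop_loss",
    "nonsense",
    "indel_fs",
    "indel_nfs",
    "intron_pm2",
]

_SNV_SEVERITY = [
    FuncClass.NONSENSE,
    FuncClass.STOP_LOSS,
    FuncClass.MISSENSE,
    FuncClass.SYNONYMOUS,
]

_CLASS_TO_COLUMN = {
    FuncClass.SYNONYMOUS: "synonymous",
    FuncClass.MISSENSE: "missense",
    FuncClass.STOP_LOSS: "stop_loss",
    FuncClass.NONSENSE: "nonsense",
    FuncClass.FRAMESHIFT: "indel_fs",
    FuncClass.NON_FRAMESHIFT: "indel_nfs",
}


def _overview_column(v: ObservedVariant) -> Optional[str]:
    """Displayed column of a variant, or None when outside the display.

    Coding annotations win over splice; among coding SNV classes the most
    severe transcript annotation decides.  UTR and intron-flank variants are
    not displayed (they stay filterable through recipes).
    """
    classes = {a.func_class for a in v.annotations if a.region is Region.CDS}
    for fc in (FuncClass.FRAMESHIFT, FuncClass.NON_FRAMESHIFT):
        if fc in classes:
            return _CLASS_TO_COLUMN[fc]
    for fc in _SNV_SEVERITY:
        if fc in classes:
            return _CLASS_TO_COLUMN[fc]
    if any(a.region is Region.SPLICE_SITE for a in v.annotations):
        return "intron_pm2"
    return None


@dataclass
class OverviewTable:
    """Per-individual counts split known/unknown x displayed category.

    Displayed categories are the six exonic classes plus the intronic
    splice dinucleotide (+/-2 bp); each variant is counted once.
    """

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def cell(self, individual_id: str, status: str, column: str) -> int:
        sel = self.rows[
            (self.rows["individual_id"] == individual_id) & (self.rows["status"] == status)
        ]
        return int(sel.iloc[0][column]) if len(sel) else 0

    def individual_total(self, individual_id: str) -> int:
        sel = self.rows[self.rows["individual_id"] == individual_id]
        return int(sel[_OVERVIEW_COLUMNS].to_numpy().sum()) if len(sel) else 0


def overview(project: Project, catalogue: Catalogue) -> OverviewTable:
    """Build the variation-overview count table against one catalogue.

    Variants are split known/unknown by catalogue membership, then tallied
    into the displayed categories.  Individuals appear in manifest order;
    projects with no individuals yield an empty table.
    """
    records = []
    for ind in project.individuals:
        counts = {
            status: {c: 0 for c in _OVERVIEW_COLUMNS} for status in ("known", "unknown")
        }
        for v in project.variants:
            if v.individual_id != ind.individual_id:
                continue
            column = _overview_column(v)
            if column is None:
                continue
            status = "known" if catalogue.contains(v.key, v.rsid) else "unknown"
            counts[status][column] += 1
        for status in ("known", "unknown"):
            records.append(
                {"individual_id": ind.individual_id, "status": status, **counts[status]}
            )
    columns = ["individual_id", "status", *_OVERVIEW_COLUMNS]
    return OverviewTable(rows=pd.DataFrame(records, columns=columns))
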