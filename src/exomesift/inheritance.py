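"""Inheritance strategies over a filtered variant set.

Three study designs are supported, mirroring common practice for rare
Mendelian disorders:

* **recurrence** across unrelated index cases — per gene, count the
  distinct carriers among the selected individuals and bin genes by their
  exact carrier count (an intersection strategy for genetically
  heterogeneous dominant or recessive disorders);
* **intra-familial sharing** — variants present in every selected relative
  with a compatible zygosity, plus unphased compound-heterozygote
  detection;
* **de novo** trio subtraction — child variants whose key is absent from
  both parents.

All operations take variants that have already been filtered (typically the
primary screen's output) and reason at the gene level through annotations.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .datamodel import ObservedVariant, VariantKey, Zygosity, genes_of
from .errors import ConfigError

__all__ = [
    "RecurrenceTable",
    "recurrence",
    "shared_family",
    "compound_heterozygous",
    "de_novo",
]


@dataclass
class RecurrenceTable:
    """Genes binned by their exact number of carrying individuals.

    ``levels[k]`` is the sorted list of genes carried by exactly ``k`` of
    the ``n_individuals`` selected individuals; levels partition the set of
    genes with at least one qualifying variant.
    """

    n_individuals: int
    levels: dict[int, list[str]] = field(default_factory=dict)

    def count(self, k: int) -> int:
        return len(self.levels.get(k, []))

    def genes_at(self, k: int) -> list[str]:
        return list(self.levels.get(k, []))

    @property
    def total_genes(self) -> int:
        return sum(len(g) for g in self.levels.values())

    def level_of(self, gene_id: str) -> Optional[int]:
        for k, genes in self.levels.items():
            if gene_id in genes:
                return k
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "n_individuals": f"{k}/{self.n_individuals}",
                "level": k,
                "n_genes": len(self.levels.get(k, [])),
                "genes": ";".join(self.levels.get(k, [])),
            }
            for k in range(self.n_individuals, 0, -1)
        ]
        return pd.DataFrame(rows, columns=["n_individuals", "level", "n_genes", "genes"])

    def _assert_partition(self) -> None:
        seen: set[str] = set()
        for k, genes in self.levels.items():
            overlap = seen & set(genes)
            if overlap:
                raise AssertionError(f"gene(s) {sorted(overlap)} in multiple levels")
            seen |= set(genes)
        if len(seen) != self.total_genes:
            raise AssertionError("duplicate genes within a level")


def _is_carrier(
    gene_variants: list[ObservedVariant], zygosity_mode: str
) -> bool:
    """Carrier test for one individual's qualifying variants in one gene.

    ``dominant`` (the default elsewhere): any qualifying variant.
    ``recessive``: at least one homozygous variant, or at least two
    distinct heterozygous keys (a potential compound heterozygote).
    """
    if zygosity_mode == "dominant":
        return bool(gene_variants)
    if zygosity_mode == "recessive":
        if any(v.zygosity is Zygosity.HOM for v in gene_variants):
            return True
        het_keys = {v.key for v in gene_variants if v.zygosity is Zygosity.HET}
        return len(het_keys) >= 2
    raise ConfigError(f"zygosity_mode must be 'dominant' or 'recessive', got {zygosity_mode!r}")


def recurrence(
    variants: Sequence[ObservedVariant],
    individuals: Sequence[str],
    zygosity_mode: str = "dominant",
) -> RecurrenceTable:
    """Bin genes by the exact number of selected individuals carrying them.

    ``carriers(gene)`` counts distinct selected individuals with at least
    one qualifying variant annotated to the gene (any variant, not the same
    one).  Levels are mutually exclusive; per-level gene lists are sorted.
    Individual order is irrelevant.
    """
    selected = list(dict.fromkeys(individuals))
    if not selected:
        raise ConfigError("recurrence requires at least one selected individual")
    sel = set(selected)
    per_gene_per_ind: dict[str, dict[str, list[ObservedVariant]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for v in variants:
        if v.individual_id not in sel:
            continue
        for gene in genes_of(v):
            per_gene_per_ind[gene][v.individual_id].append(v)

    levels: dict[int, list[str]] = defaultdict(list)
    for gene, by_ind in per_gene_per_ind.items():
        carriers = sum(
            1 for vs in by_ind.values() if _is_carrier(vs, zygosity_mode)
        )
        if carriers:
            levels[carriers].append(gene)
    table = RecurrenceTable(
        n_individuals=len(selected),
        levels={k: sorted(genes) for k, genes in levels.items()},
    )
    table._assert_partition()
    return table


def shared_family(
    variants: Sequence[ObservedVariant],
    family_individuals: Sequence[str],
    zygosity_mode: str = "EITHER",
) -> dict[str, list[VariantKey]]:
    """Variants shared by every selected relative, grouped by gene.

    A key qualifies when each selected individual carries it with a
    zygosity matching ``zygosity_mode`` (``HOM``, ``HET`` or ``EITHER``).
    Returns gene -> sorted list of shared keys.
    """
    members = list(dict.fromkeys(family_individuals))
    if len(members) < 2:
        raise ConfigError("shared_family requires at least two related individuals")
    mode = zygosity_mode.upper()
    if mode not in {"HOM", "HET", "EITHER"}:
        raise ConfigError(f"zygosity_mode must be HOM, HET or EITHER, got {zygosity_mode!r}")

    def matches(v: ObservedVariant) -> bool:
        return mode == "EITHER" or v.zygosity.value == mode

    per_key: dict[VariantKey, dict[str, ObservedVariant]] = defaultdict(dict)
    for v in variants:
        if v.individual_id in members and matches(v):
            per_key[v.key][v.individual_id] = v

    out: dict[str, set[VariantKey]] = defaultdict(set)
    for key, carriers in per_key.items():
        if set(carriers) >= set(members):
            genes = set()
            for v in carriers.values():
                genes |= genes_of(v)
            for gene in genes:
                out[gene].add(key)
    return {gene: sorted(keys) for gene, keys in sorted(out.items())}


def compound_heterozygous(
    variants: Sequence[ObservedVariant],
    individual: str,
    father_variants: Optional[Sequence[ObservedVariant]] = None,
    mother_variants: Optional[Sequence[ObservedVariant]] = None,
) -> dict[str, list[VariantKey]]:
    """Genes with >= 2 distinct heterozygous keys in one individual.

    Without parental data every such gene is reported (unphased,
    conservative superset).  When both parents' variant collections are
    supplied, genes whose candidate keys all trace to a single parent are
    removed: two variants inherited through one chromosome cannot be in
    trans (phase-by-transmission).
    """
    per_gene: dict[str, set[VariantKey]] = defaultdict(set)
    for v in variants:
        if v.individual_id == individual and v.zygosity is Zygosity.HET:
            for gene in genes_of(v):
                per_gene[gene].add(v.key)
    candidates = {g: sorted(ks) for g, ks in per_gene.items() if len(ks) >= 2}

    if father_variants is not None and mother_variants is not None:
        father_keys = {v.key for v in father_variants}
        mother_keys = {v.key for v in mother_variants}
        candidates = {
            g: ks
            for g, ks in candidates.items()
            if not (all(k in father_keys for k in ks) or all(k in mother_keys for k in ks))
        }
    return dict(sorted(candidates.items()))


def de_novo(
    child_variants: Sequence[ObservedVariant],
    father_variants: Optional[Sequence[ObservedVariant]],
    mother_variants: Optional[Sequence[ObservedVariant]],
) -> list[ObservedVariant]:
    """Child variants absent (at any zygosity) from both parents.

    Matching is by normalized key only: a parent carrying the key at any
    zygosity, quality or coverage contradicts a de novo origin.  Symmetric
    in the two parents.  Passing ``None`` for a parent is a config error —
    an unsequenced parent cannot be subtracted.
    """
    if father_variants is None or mother_variants is None:
        raise ConfigError("de_novo requires both parental variant collections")
    parental_keys = {v.key for v in father_variants} | {v.key for v in mother_variants}
    return [v for v in child_variants if v.key not in parental_keys]
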