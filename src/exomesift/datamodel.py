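"""Core domain types for exome variant projects.

The model mirrors a relational exome store: variants (normalized genomic
identity), per-individual observations (genotype, quality, coverage), gene
and transcript annotations, and individuals grouped into families.

Coordinates are 1-based, fully closed, as in VCF.  Indels are stored
VCF-style with the anchor base included; :func:`normalize_variant` is the
single place where variant identity is canonicalized, so catalogue lookups
and cross-individual comparisons are well-defined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .errors import (
    ConfigError,
    InvalidAlleleError,
    NullVariantError,
    UnsupportedVariantError,
)

__all__ = [
    "VariantType",
    "Zygosity",
    "Region",
    "FuncClass",
    "Role",
    "VariantKey",
    "FunctionalAnnotation",
    "ObservedVariant",
    "Individual",
    "Project",
    "normalize_variant",
    "normalize_chrom",
    "genes_of",
    "CHROMOSOMES",
    "chrom_sort_key",
]

_VALID_BASES = frozenset("ACGT")

#: Canonical chromosome vocabulary, in karyotype order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}


class VariantType(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "INSERTION"
    DELETION = "DELETION"


class Zygosity(str, enum.Enum):
    HET = "HET"
    HOM = "HOM"


class Region(str, enum.Enum):
    """Genic region of an annotation.

    SPLICE_SITE covers the two intronic bases flanking an exon (the
    donor/acceptor dinucleotide); INTRON_FLANK covers intronic positions
    3-20 bp from the nearest exon boundary, the deepest intronic positions
    retained by exome capture annotation.
    """

    CDS = "CDS"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    SPLICE_SITE = "SPLICE_SITE"
    INTRON_FLANK = "INTRON_FLANK"


class FuncClass(str, enum.Enum):
    """Functional class: four SNV classes, two indel classes, or NONE.

    SYNONYMOUS/MISSENSE/STOP_LOSS/NONSENSE apply to coding SNVs;
    FRAMESHIFT/NON_FRAMESHIFT to coding indels; NONE to everything
    non-coding (UTR, splice site, intron flank).
    """

    SYNONYMOUS = "SYNONYMOUS"
    MISSENSE = "MISSENSE"
    STOP_LOSS = "STOP_LOSS"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    NON_FRAMESHIFT = "NON_FRAMESHIFT"
    NONE = "NONE"


class Role(str, enum.Enum):
    INDEX = "INDEX"
    MOTHER = "MOTHER"
    FATHER = "FATHER"
    SIBLING = "SIBLING"
    OTHER = "OTHER"


def normalize_chrom(chrom: str) -> str:
    """Canonicalize a chromosome label: strip any 'chr' prefix, map M->MT."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    if c == "M":
        c = "MT"
    if c not in _CHROM_ORDER:
        raise InvalidAlleleError(f"unknown chromosome label: {chrom!r}")
    return c


def chrom_sort_key(chrom: str) -> int:
    """Karyotype ordering 1..22, X, Y, MT for deterministic output."""
    return _CHROM_ORDER[chrom]


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized genomic identity of a variant.

    Equality over all five fields; construct via :func:`normalize_variant`
    rather than directly so the trimming invariants hold.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: VariantType = field(compare=True)

    def __str__(self) -> str:  # chrom:pos:ref>alt, handy in logs/CSV
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def signed_length(self) -> int:
        """len(alt) - len(ref): 0 for SNV, >0 insertion, <0 deletion."""
        return len(self.alt) - len(self.ref)


def _check_allele(allele: str, label: str) -> str:
    a = str(allele).upper()
    if not a or not set(a) <= _VALID_BASES:
        raise InvalidAlleleError(f"{label} allele {allele!r} is not a non-empty ACGT string")
    return a


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Canonicalize a (chrom, pos, ref, alt) quadruple into a VariantKey.

    Shared suffix bases are trimmed first, then shared prefix bases (keeping
    at least one base per allele, so indels stay anchored VCF-style with the
    position advanced past trimmed prefix bases).  Idempotent: normalizing a
    normalized key returns an equal key.

    Raises
    ------
    InvalidAlleleError
        non-ACGT or empty allele
    NullVariantError
        ref == alt (before or after trimming)
    UnsupportedVariantError
        trimmed alleles form a multi-nucleotide substitution (not SNV/indel)
    """
    c = normalize_chrom(chrom)
    p = int(pos)
    if p < 1:
        raise InvalidAlleleError(f"position must be >= 1, got {pos}")
    r = _check_allele(ref, "ref")
    a = _check_allele(alt, "alt")
    if r == a:
        raise NullVariantError(f"ref and alt are identical ({r!r}) at {c}:{p}")

    # trim shared suffix, keeping one base in each allele
    while len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    # trim shared prefix, advancing the position
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        r, a = r[1:], a[1:]
        p += 1

    if r == a:
        raise NullVariantError(f"alleles identical after trimming at {c}:{p}")
    if len(r) == 1 and len(a) == 1:
        vt = VariantType.SNV
    elif len(a) > len(r):
        vt = VariantType.INSERTION
    elif len(a) < len(r):
        vt = VariantType.DELETION
    else:
        raise UnsupportedVariantError(
            f"multi-nucleotide substitution {r}>{a} at {c}:{p} is not supported"
        )
    return VariantKey(c, p, r, a, vt)


@dataclass(frozen=True)
class FunctionalAnnotation:
    """Gene/transcript context of a variant on one transcript."""

    gene_id: str
    gene_symbol: str
    transcript: str
    region: Region
    region_index: Optional[int] = None
    func_class: FuncClass = FuncClass.NONE
    codon_ref: Optional[str] = None
    codon_alt: Optional[str] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    protein_pos: Optional[int] = None


@dataclass(frozen=True)
class ObservedVariant:
    """A normalized variant observed in one individual.

    ``annotations`` holds one entry per affected transcript; it may be empty
    immediately after reading an un-annotated VCF, but every operation that
    reasons at gene level (``genes_of``, the inheritance strategies) requires
    at least one annotation.
    """

    key: VariantKey
    individual_id: str
    zygosity: Zygosity
    quality: float = 0.0
    coverage: int = 0
    rsid: Optional[str] = None
    annotations: tuple[FunctionalAnnotation, ...] = ()
    filter_flag: Optional[str] = None  # non-PASS VCF FILTER value, kept but flagged

    def with_annotations(self, annotations: Iterable[FunctionalAnnotation]) -> "ObservedVariant":
        return replace(self, annotations=tuple(annotations))


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: Optional[str] = None
    role: Role = Role.OTHER
    affected: bool = False


@dataclass
class Project:
    """An exome project: individuals, their variants, and a genome build."""

    name: str
    genome_build: str = "GRCh37"
    individuals: list[Individual] = field(default_factory=list)
    variants: list[ObservedVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [ind.individual_id for ind in self.individuals]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate individual_id in project")
        known = set(ids)
        for v in self.variants:
            if v.individual_id not in known:
                raise ConfigError(
                    f"variant {v.key} observed in unknown individual {v.individual_id!r}"
                )

    def individual(self, individual_id: str) -> Individual:
        for ind in self.individuals:
            if ind.individual_id == individual_id:
                return ind
        raise ConfigError(f"unknown individual {individual_id!r}")

    def variants_of(self, individual_id: str) -> list[ObservedVariant]:
        self.individual(individual_id)  # raises on unknown id
        return [v for v in self.variants if v.individual_id == individual_id]

    def trio(self, family_id: str) -> tuple[Individual, Individual, Individual]:
        """Return (index, father, mother) for a family, validating trio shape."""
        members = [i for i in self.individuals if i.family_id == family_id]
        index = [i for i in members if i.role is Role.INDEX and i.affected]
        father = [i for i in members if i.role is Role.FATHER]
        mother = [i for i in members if i.role is Role.MOTHER]
        if len(index) != 1 or len(father) != 1 or len(mother) != 1:
            raise ConfigError(
                f"family {family_id!r} is not a trio "
                f"(affected INDEX={len(index)}, FATHER={len(father)}, MOTHER={len(mother)})"
            )
        return index[0], father[0], mother[0]


def genes_of(variant: ObservedVariant) -> set[str]:
    """Distinct gene_ids over all annotations of a variant."""
    if not variant.annotations:
        raise ConfigError(f"variant {variant.key} has no annotations")
    return {ann.gene_id for ann in variant.annotations}


def variant_sort_key(v: ObservedVariant) -> tuple:
    """Deterministic (chrom, pos, ref, alt, individual) ordering."""
    return (chrom_sort_key(v.key.chrom), v.key.pos, v.key.ref, v.key.alt, v.individual_id)
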