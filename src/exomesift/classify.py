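"""Variant taxonomy: known/unknown partition, functional class, genic region.

Coding SNVs fall into four classes (synonymous, missense, stop loss,
nonsense) from the reference/alternate codon pair under the standard nuclear
genetic code; coding indels are frameshift or non-frameshift from the length
change modulo 3.  Genic regions distinguish CDS, the two UTRs, the splice
dinucleotide (intronic positions 1-2 from an exon boundary) and the retained
intron flank (positions 3-20); deeper intronic positions are outside the
captured window and rejected.

When input files already carry a functional class the classifier validates
rather than recomputes: discordance is reported and the file's value wins
(see :func:`validate_annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .datamodel import (
    FuncClass,
    FunctionalAnnotation,
    ObservedVariant,
    Region,
    VariantKey,
    VariantType,
)
from .errors import InvalidCodonPairError, OutOfCaptureError, WrongTypeError

__all__ = [
    "GENETIC_CODE",
    "STOP",
    "GeneModel",
    "translate_codon",
    "classify_snv",
    "classify_indel",
    "assign_region",
    "partition_known",
    "validate_annotation",
]

STOP = "*"

# Standard nuclear genetic code (translation table 1).
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": STOP, "TAG": STOP,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": STOP, "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_codon(codon: str) -> str:
    """One-letter amino acid (or ``*`` for stop) of an ACGT codon."""
    c = codon.upper()
    if c not in GENETIC_CODE:
        raise InvalidCodonPairError(f"not a valid ACGT codon: {codon!r}")
    return GENETIC_CODE[c]


def classify_snv(codon_ref: str, codon_alt: str) -> FuncClass:
    """Functional class of a coding SNV from its codon pair.

    The codons must differ at exactly one position.  Classes:
    SYNONYMOUS (same residue, including stop->stop), NONSENSE (residue to
    stop), STOP_LOSS (stop to residue), MISSENSE (residue to different
    residue).
    """
    aa_ref = translate_codon(codon_ref)
    aa_alt = translate_codon(codon_alt)
    diffs = sum(a != b for a, b in zip(codon_ref.upper(), codon_alt.upper()))
    if diffs != 1:
        raise InvalidCodonPairError(
            f"codons {codon_ref}/{codon_alt} differ at {diffs} positions, expected 1"
        )
    if aa_ref == aa_alt:
        return FuncClass.SYNONYMOUS
    if aa_alt == STOP:
        return FuncClass.NONSENSE
    if aa_ref == STOP:
        return FuncClass.STOP_LOSS
    return FuncClass.MISSENSE


def classify_indel(key: VariantKey, region: Region) -> FuncClass:
    """FRAMESHIFT / NON_FRAMESHIFT for coding indels, NONE outside the CDS."""
    if key.vtype is VariantType.SNV:
        raise WrongTypeError(f"classify_indel called on SNV {key}")
    if region is not Region.CDS:
        return FuncClass.NONE
    return (
        FuncClass.FRAMESHIFT
        if abs(key.signed_length) % 3 != 0
        else FuncClass.NON_FRAMESHIFT
    )


@dataclass(frozen=True)
class GeneModel:
    """Minimal transcript model: ordered exons, CDS bounds, strand.

    Exons are 1-based closed genomic intervals sorted by position and
    non-overlapping; ``cds_start``/``cds_end`` are genomic bounds lying
    inside the exon span.  ``sequence`` (reference sequence of the locus,
    starting at the first exon's start) is only needed when codons are to be
    computed, which the classifier itself never requires.
    """

    gene_id: str
    transcript: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    gene_symbol: Optional[str] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon ({s},{e}) has start > end")
            if prev_end is not None and s <= prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e
        if not (self.exons[0][0] <= self.cds_start <= self.cds_end <= self.exons[-1][1]):
            raise ValueError("CDS bounds outside the exon span")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exon_ordinal(self, i: int) -> int:
        """Genomic exon index -> ordinal along the gene (strand-aware, 1-based)."""
        n = len(self.exons)
        return i + 1 if self.strand == "+" else n - i


#: Intronic bases retained by exome capture annotation, per intron boundary.
INTRON_WINDOW = 20
#: Intronic bases counted as the splice donor/acceptor dinucleotide.
SPLICE_WINDOW = 2


def assign_region(key: VariantKey, gene_model: GeneModel) -> tuple[Region, int]:
    """Genic region and exon/intron ordinal of a position in a gene model.

    Exonic positions are CDS or UTR (5' vs 3' decided by strand); intronic
    positions 1-2 bp from the nearest exon boundary are SPLICE_SITE, 3-20 bp
    are INTRON_FLANK, deeper ones raise :class:`OutOfCaptureError`.  The
    variant is located by its anchor position.
    """
    pos = key.pos
    exons = gene_model.exons
    lo, hi = gene_model.span
    if pos < lo or pos > hi:
        raise OutOfCaptureError(
            f"position {key.chrom}:{pos} outside locus span {lo}-{hi} of "
            f"{gene_model.gene_id}"
        )
    for i, (s, e) in enumerate(exons):
        if s <= pos <= e:
            if gene_model.cds_start <= pos <= gene_model.cds_end:
                return Region.CDS, gene_model.exon_ordinal(i)
            upstream_of_cds = pos < gene_model.cds_start
            if gene_model.strand == "+":
                region = Region.UTR5 if upstream_of_cds else Region.UTR3
            else:
                region = Region.UTR3 if upstream_of_cds else Region.UTR5
            return region, gene_model.exon_ordinal(i)
    # intronic: find the flanking exon pair
    for i in range(len(exons) - 1):
        left_end = exons[i][1]
        right_start = exons[i + 1][0]
        if left_end < pos < right_start:
            dist = min(pos - left_end, right_start - pos)
            # intron ordinal follows the upstream exon along the gene
            if gene_model.strand == "+":
                ordinal = i + 1
            else:
                ordinal = len(exons) - 1 - i
            if dist <= SPLICE_WINDOW:
                return Region.SPLICE_SITE, ordinal
            if dist <= INTRON_WINDOW:
                return Region.INTRON_FLANK, ordinal
            raise OutOfCaptureError(
                f"position {key.chrom}:{pos} is {dist} bp into intron {ordinal} "
                f"of {gene_model.gene_id}, beyond the +/-{INTRON_WINDOW} bp window"
            )
    raise OutOfCaptureError(f"position {key.chrom}:{pos} not locatable in {gene_model.gene_id}")


def partition_known(
    variants: Sequence[ObservedVariant], catalogue
) -> tuple[list[ObservedVariant], list[ObservedVariant]]:
    """Split variants into (known, unknown) by catalogue membership.

    Every input variant lands in exactly one list; order is preserved.
    """
    known: list[ObservedVariant] = []
    unknown: list[ObservedVariant] = []
    for v in variants:
        (known if catalogue.contains(v.key, v.rsid) else unknown).append(v)
    return known, unknown


def validate_annotation(
    key: VariantKey, annotation: FunctionalAnnotation
) -> list[str]:
    """Check a file-supplied annotation against the classifier's own rules.

    Returns a list of discordance messages (empty when concordant).  The
    file's values are never altered — upstream annotation wins — but the
    messages let ingest report suspicious rows.
    """
    issues: list[str] = []
    fc = annotation.func_class
    if key.vtype is VariantType.SNV:
        if fc in {FuncClass.FRAMESHIFT, FuncClass.NON_FRAMESHIFT}:
            issues.append(f"{key}: SNV carries indel class {fc.value}")
        if annotation.codon_ref and annotation.codon_alt:
            try:
                expected = classify_snv(annotation.codon_ref, annotation.codon_alt)
            except InvalidCodonPairError as exc:
                issues.append(f"{key}: bad codon pair ({exc})")
            else:
                if fc is not FuncClass.NONE and fc is not expected:
                    issues.append(
                        f"{key}: file class {fc.value} != recomputed {expected.value} "
                        f"({annotation.codon_ref}>{annotation.codon_alt})"
                    )
    else:
        if fc in {
            FuncClass.SYNONYMOUS,
            FuncClass.MISSENSE,
            FuncClass.STOP_LOSS,
            FuncClass.NONSENSE,
        }:
            issues.append(f"{key}: indel carries SNV class {fc.value}")
        else:
            expected = classify_indel(key, annotation.region)
            if fc is not FuncClass.NONE and fc is not expected:
                issues.append(
                    f"{key}: file class {fc.value} != recomputed {expected.value}"
                )
    if fc in {
        FuncClass.SYNONYMOUS,
        FuncClass.MISSENSE,
        FuncClass.STOP_LOSS,
        FuncClass.NONSENSE,
        FuncClass.FRAMESHIFT,
        FuncClass.NON_FRAMESHIFT,
    } and annotation.region is not Region.CDS:
        issues.append(
            f"{key}: coding class {fc.value} on non-CDS region {annotation.region.value}"
        )
    return issues
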