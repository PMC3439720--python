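"""Variation statistics: count distributions, Ti/Tv and the amino-acid
substitution matrix.

Everything is computed as a plain table (pandas) so summaries run headless;
chart rendering, when wanted, is a thin matplotlib layer the caller owns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .classify import STOP, translate_codon
from .datamodel import (
    CHROMOSOMES,
    FuncClass,
    ObservedVariant,
    Region,
    VariantType,
)
from .errors import ConfigError

__all__ = [
    "SubstitutionSummary",
    "AAMatrix",
    "AA_ALPHABET",
    "titv",
    "distribution",
    "aa_matrix",
]

_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})
_BASES = "ACGT"
_ORDERED_PAIRS = [(r, a) for r in _BASES for a in _BASES if r != a]

#: 20 amino acids plus the stop symbol, rows/columns of the AA matrix.
AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY") + (STOP,)


@dataclass
class SubstitutionSummary:
    """Transition/transversion tally over a set of SNVs.

    ``per_substitution`` holds one count per ordered ref->alt base pair (12
    cells); ``titv_ratio`` is None when no transversion was seen.
    ``skipped`` counts non-SNV records ignored by the tally.
    """

    ti_count: int = 0
    tv_count: int = 0
    per_substitution: dict[tuple[str, str], int] = field(
        default_factory=lambda: {p: 0 for p in _ORDERED_PAIRS}
    )
    skipped: int = 0

    @property
    def titv_ratio(self) -> Optional[float]:
        return self.ti_count / self.tv_count if self.tv_count else None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ref": r,
                "alt": a,
                "count": self.per_substitution[(r, a)],
                "kind": "transition" if (r, a) in _TRANSITIONS else "transversion",
            }
            for r, a in _ORDERED_PAIRS
        ]
        return pd.DataFrame(rows)


def titv(variants: Sequence[ObservedVariant]) -> SubstitutionSummary:
    """Classify each SNV's ordered base substitution and form Ti/Tv.

    Transitions are A<->G and C<->T; every other pairing is a
    transversion.  Non-SNV inputs are ignored and counted in ``skipped``.
    The invariant ti + tv = number of SNVs summarized is asserted on every
    call.
    """
    summary = SubstitutionSummary()
    n_snv = 0
    for v in variants:
        if v.key.vtype is not VariantType.SNV:
            summary.skipped += 1
            continue
        pair = (v.key.ref, v.key.alt)
        summary.per_substitution[pair] += 1
        if pair in _TRANSITIONS:
            summary.ti_count += 1
        else:
            summary.tv_count += 1
        n_snv += 1
    assert summary.ti_count + summary.tv_count == n_snv
    return summary


_AXES = {"chromosome", "region", "func_class", "individual", "indel_length"}


def distribution(variants: Sequence[ObservedVariant], by: str) -> pd.DataFrame:
    """Count variants along one axis.

    ``by`` is one of chromosome, region, func_class, individual or
    indel_length.  Fixed vocabularies (chromosomes, regions, classes) list
    zero-count labels; open vocabularies (individuals, signed indel
    lengths) list observed labels only.  Region and class axes count one
    annotation-derived label per variant (the first annotation), and
    variants without annotations are reported under the ``dropped`` column
    convention: the returned frame's attrs carry ``n_input`` and
    ``n_dropped``.
    """
    if by not in _AXES:
        raise ConfigError(f"unknown distribution axis {by!r}; choose from {sorted(_AXES)}")
    counts: Counter = Counter()
    dropped = 0
    for v in variants:
        if by == "chromosome":
            counts[v.key.chrom] += 1
        elif by == "individual":
            counts[v.individual_id] += 1
        elif by == "indel_length":
            if v.key.vtype is VariantType.SNV:
                dropped += 1
            else:
                counts[v.key.signed_length] += 1
        elif by == "region":
            if v.annotations:
                counts[v.annotations[0].region.value] += 1
            else:
                dropped += 1
        elif by == "func_class":
            if v.annotations:
                counts[v.annotations[0].func_class.value] += 1
            else:
                dropped += 1

    if by == "chromosome":
        labels = list(CHROMOSOMES)
    elif by == "region":
        labels = [r.value for r in Region]
    elif by == "func_class":
        labels = [c.value for c in FuncClass]
    else:
        labels = sorted(counts)
    df = pd.DataFrame({by: labels, "count": [counts.get(l, 0) for l in labels]})
    df.attrs["n_input"] = len(variants)
    df.attrs["n_dropped"] = dropped
    return df


@dataclass
class AAMatrix:
    """21x21 amino-acid substitution count matrix (rows = reference).

    The diagonal collects synonymous changes; ``skipped`` counts CDS SNVs
    lacking both codon and amino-acid annotation.
    """

    matrix: pd.DataFrame
    skipped: int = 0

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def cell(self, aa_ref: str, aa_alt: str) -> int:
        return int(self.matrix.loc[aa_ref, aa_alt])

    def to_frame(self) -> pd.DataFrame:
        out = self.matrix.copy()
        out.insert(0, "aa_ref", out.index)
        return out.reset_index(drop=True)


def _aa_pair(v: ObservedVariant) -> Optional[tuple[str, str]]:
    """First CDS-SNV annotation's (aa_ref, aa_alt), from residues or codons."""
    for ann in v.annotations:
        if ann.region is not Region.CDS:
            continue
        if ann.aa_ref and ann.aa_alt:
            return ann.aa_ref, ann.aa_alt
        if ann.codon_ref and ann.codon_alt:
            return translate_codon(ann.codon_ref), translate_codon(ann.codon_alt)
    return None


def aa_matrix(variants: Sequence[ObservedVariant]) -> AAMatrix:
    """Accumulate amino-acid substitution counts over coding SNVs.

    Each CDS SNV contributes one ordered (reference residue, variant
    residue) cell, taken from its first coding annotation; CDS SNVs with
    neither residues nor codons recorded are skipped and counted.
    """
    mat = pd.DataFrame(0, index=list(AA_ALPHABET), columns=list(AA_ALPHABET), dtype=int)
    skipped = 0
    for v in variants:
        if v.key.vtype is not VariantType.SNV:
            continue
        if not any(a.region is Region.CDS for a in v.annotations):
            continue
        pair = _aa_pair(v)
        if pair is None:
            skipped += 1
            continue
        aa_ref, aa_alt = pair
        if aa_ref not in AA_ALPHABET or aa_alt not in AA_ALPHABET:
            skipped += 1
            continue
        mat.loc[aa_ref, aa_alt] += 1
    return AAMatrix(matrix=mat, skipped=skipped)
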