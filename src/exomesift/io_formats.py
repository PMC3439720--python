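"""Readers and writers for the project's on-disk formats.

Supported inputs: VCF 4.x (one or many samples, read through cyvcf2), a
tab-delimited annotated dialect (one row per variant x transcript), known
variant catalogues (VCF or plain key/rsID lists), BED12 toy gene models and
a YAML project manifest.  The only writer is RFC-4180 CSV for result tables.

Annotations travel inside VCF through a structured INFO field ``TXA``
(transcript annotation), one ``|``-joined entry per transcript::

    allele|gene_id|gene_symbol|transcript|region|region_index|func_class|
    codon_ref|codon_alt|aa_ref|aa_alt|protein_pos

with ``.`` for absent sub-fields and entries separated by commas, so a VCF
and an annotated TSV written from the same observations decode to identical
in-memory variant sets.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from cyvcf2 import VCF

from .classify import GeneModel
from .datamodel import (
    FuncClass,
    FunctionalAnnotation,
    Individual,
    ObservedVariant,
    Project,
    Region,
    Role,
    VariantKey,
    Zygosity,
    normalize_variant,
)
from .errors import (
    ConfigError,
    ExomeSiftError,
    FormatError,
    RowError,
    SampleNotFoundError,
    SchemaError,
)

__all__ = [
    "Catalogue",
    "ANNOTATION_INFO_FIELD",
    "TSV_COLUMNS",
    "read_vcf",
    "read_annotated_table",
    "load_catalogue",
    "export_csv",
    "read_gene_models_bed12",
    "Manifest",
    "ManifestEntry",
    "read_manifest",
    "load_project",
]

ANNOTATION_INFO_FIELD = "TXA"

#: Column order of the annotated tab-delimited dialect (one row per
#: variant x transcript; absent optional values are written as ``.``).
TSV_COLUMNS = [
    "individual_id",
    "chrom",
    "position",
    "ref",
    "alt",
    "genotype",
    "quality",
    "coverage",
    "rsid",
    "gene_id",
    "gene_symbol",
    "transcript",
    "region",
    "region_index",
    "func_class",
    "codon_ref",
    "codon_alt",
    "aa_ref",
    "aa_alt",
    "protein_pos",
]

_MANDATORY_COLUMNS = TSV_COLUMNS[:6]

_GENOTYPE_TOKENS = {
    "het": Zygosity.HET,
    "heterozygous": Zygosity.HET,
    "hom": Zygosity.HOM,
    "homozygous": Zygosity.HOM,
}


# ---------------------------------------------------------------------------
# catalogues


@dataclass(frozen=True)
class Catalogue:
    """An immutable set of known variants, queryable by key and/or rsID.

    ``match`` selects the membership policy: ``key`` (normalized key only),
    ``rsid`` (rsID only) or ``either`` (union — the default, since public
    catalogues mix positional records and rsID-only records).
    """

    name: str
    keys: frozenset[VariantKey] = frozenset()
    rsids: frozenset[str] = frozenset()
    match: str = "either"

    def __post_init__(self) -> None:
        if self.match not in {"key", "rsid", "either"}:
            raise ConfigError(f"unknown catalogue match policy {self.match!r}")

    def contains(self, key: VariantKey, rsid: Optional[str] = None) -> bool:
        by_key = key in self.keys
        by_rsid = rsid is not None and rsid in self.rsids
        if self.match == "key":
            return by_key
        if self.match == "rsid":
            return by_rsid
        return by_key or by_rsid

    def __len__(self) -> int:
        return len(self.keys) + len(self.rsids - {None})


def load_catalogue(path: str | os.PathLike, name: str, match: str = "either") -> Catalogue:
    """Load a catalogue from a VCF or a plain-text key/rsID list.

    Text lists hold one entry per line: either ``chrom<TAB>pos<TAB>ref<TAB>alt``
    or a bare ``rs...`` identifier.  Duplicates are deduplicated.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"catalogue file not found: {p}")
    keys: set[VariantKey] = set()
    rsids: set[str] = set()
    if p.suffix.lower() in {".vcf", ".gz", ".bcf"}:
        vcf = VCF(str(p))
        try:
            for rec in vcf:
                for alt in rec.ALT:
                    keys.add(normalize_variant(rec.CHROM, rec.POS, rec.REF, alt))
                if rec.ID and rec.ID.startswith("rs"):
                    rsids.add(rec.ID)
        finally:
            vcf.close()
    else:
        with open(p) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) == 4:
                    keys.add(normalize_variant(parts[0], int(parts[1]), parts[2], parts[3]))
                elif len(parts) == 1 and parts[0].startswith("rs"):
                    rsids.add(parts[0])
                else:
                    raise FormatError(
                        f"{p}:{lineno}: expected 'chrom<TAB>pos<TAB>ref<TAB>alt' "
                        f"or a bare rsID, got {line!r}"
                    )
    return Catalogue(name=name, keys=frozenset(keys), rsids=frozenset(rsids), match=match)


# ---------------------------------------------------------------------------
# annotation encoding shared by the VCF INFO field and the simulator


def _opt(value) -> str:
    return "." if value is None or value == "" else str(value)


def _unopt(token: str) -> Optional[str]:
    return None if token in {".", ""} else token


def encode_annotation(allele: str, ann: FunctionalAnnotation) -> str:
    """One TXA entry for one transcript annotation of one alt allele."""
    return "|".join(
        [
            allele,
            ann.gene_id,
            _opt(ann.gene_symbol),
            ann.transcript,
            ann.region.value,
            _opt(ann.region_index),
            ann.func_class.value,
            _opt(ann.codon_ref),
            _opt(ann.codon_alt),
            _opt(ann.aa_ref),
            _opt(ann.aa_alt),
            _opt(ann.protein_pos),
        ]
    )


def decode_annotation(entry: str) -> tuple[str, FunctionalAnnotation]:
    parts = entry.split("|")
    if len(parts) != 12:
        raise FormatError(f"malformed {ANNOTATION_INFO_FIELD} entry: {entry!r}")
    allele = parts[0]
    region_index = _unopt(parts[5])
    protein_pos = _unopt(parts[11])
    ann = FunctionalAnnotation(
        gene_id=parts[1],
        gene_symbol=_unopt(parts[2]) or parts[1],
        transcript=parts[3],
        region=Region(parts[4]),
        region_index=int(region_index) if region_index is not None else None,
        func_class=FuncClass(parts[6]),
        codon_ref=_unopt(parts[7]),
        codon_alt=_unopt(parts[8]),
        aa_ref=_unopt(parts[9]),
        aa_alt=_unopt(parts[10]),
        protein_pos=int(protein_pos) if protein_pos is not None else None,
    )
    return allele, ann


# ---------------------------------------------------------------------------
# VCF reader


def read_vcf(
    path: str | os.PathLike,
    sample: Optional[str] = None,
    annotation_field: str = ANNOTATION_INFO_FIELD,
) -> list[ObservedVariant]:
    """Read ObservedVariants from a VCF file.

    Multi-allelic records are split into one observation per alternate
    allele before normalization.  Genotypes 0/1 (one copy of the allele)
    map to HET, 1/1 to HOM; 0/0 and ./. emit nothing.  QUAL becomes the
    variant quality, FORMAT/DP (falling back to INFO/DP) the coverage, and
    an ID starting with ``rs`` the rsid.  Records failing FILTER are kept
    with ``filter_flag`` set; quality filtering is a recipe concern.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"VCF file not found: {p}")
    vcf = VCF(str(p))
    try:
        samples = list(vcf.samples)
        if sample is not None:
            if sample not in samples:
                raise SampleNotFoundError(
                    f"sample {sample!r} not in {p.name} (has {samples})"
                )
            wanted = [samples.index(sample)]
        else:
            wanted = list(range(len(samples)))
        if not samples:
            raise FormatError(f"{p.name} carries no sample columns")

        out: list[ObservedVariant] = []
        for rec in vcf:
            # htslib hands QUAL back as float32; round off the representation
            # noise so both dialects decode to identical observations
            quality = round(float(rec.QUAL), 4) if rec.QUAL is not None else 0.0
            rsid = rec.ID if rec.ID and rec.ID.startswith("rs") else None
            filter_flag = rec.FILTER  # None for PASS / '.'
            raw_txa = rec.INFO.get(annotation_field)
            if isinstance(raw_txa, tuple):
                raw_txa = ",".join(raw_txa)
            ann_by_allele: dict[str, list[FunctionalAnnotation]] = {}
            if raw_txa:
                for entry in str(raw_txa).split(","):
                    allele, ann = decode_annotation(entry)
                    ann_by_allele.setdefault(allele, []).append(ann)

            try:
                dp_fmt = rec.format("DP")
            except KeyError:  # FORMAT/DP absent from the header
                dp_fmt = None
            info_dp = rec.INFO.get("DP")
            for alt_index, alt in enumerate(rec.ALT):
                allele_number = alt_index + 1
                key = normalize_variant(rec.CHROM, rec.POS, rec.REF, alt)
                annotations = tuple(ann_by_allele.get(alt, ()))
                for si in wanted:
                    gt = rec.genotypes[si]
                    calls = [a for a in gt[:-1] if a is not None and a >= 0]
                    copies = sum(1 for a in calls if a == allele_number)
                    if copies == 0:
                        continue
                    zygosity = Zygosity.HOM if copies >= 2 else Zygosity.HET
                    if dp_fmt is not None:
                        coverage = int(dp_fmt[si][0])
                    elif info_dp is not None:
                        coverage = int(info_dp)
                    else:
                        coverage = 0
                    out.append(
                        ObservedVariant(
                            key=key,
                            individual_id=samples[si],
                            zygosity=zygosity,
                            quality=quality,
                            coverage=coverage,
                            rsid=rsid,
                            annotations=annotations,
                            filter_flag=filter_flag,
                        )
                    )
        return out
    finally:
        vcf.close()


# ---------------------------------------------------------------------------
# annotated tab-delimited dialect


def read_annotated_table(path: str | os.PathLike) -> list[ObservedVariant]:
    """Read the annotated tab-delimited dialect.

    One row per (variant, individual, transcript); rows of the same variant
    and individual are aggregated into a single ObservedVariant carrying one
    annotation per transcript row.  Rows with unparseable mandatory fields
    are collected with their line numbers and reported; the read aborts only
    when more than 10% of data rows fail.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"annotated table not found: {p}")
    df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{p.name}: missing mandatory column(s) {missing}")

    grouped: dict[tuple, dict] = {}
    bad_rows: list[str] = []
    n_rows = len(df)
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        rec = dict(zip(df.columns, row))
        try:
            key = normalize_variant(
                rec["chrom"], int(rec["position"]), rec["ref"], rec["alt"]
            )
            token = rec["genotype"].strip().lower()
            if token not in _GENOTYPE_TOKENS:
                raise FormatError(f"malformed genotype token {rec['genotype']!r}")
            zygosity = _GENOTYPE_TOKENS[token]
        except (ExomeSiftError, ValueError) as exc:
            bad_rows.append(f"line {idx}: {exc}")
            continue
        quality = float(rec.get("quality") or 0)
        coverage = int(float(rec.get("coverage") or 0))
        rsid = _unopt(rec.get("rsid", "."))
        gk = (key, rec["individual_id"])
        slot = grouped.setdefault(
            gk,
            {
                "zygosity": zygosity,
                "quality": quality,
                "coverage": coverage,
                "rsid": rsid,
                "annotations": [],
            },
        )
        gene_id = _unopt(rec.get("gene_id", "."))
        if gene_id is not None:
            region_index = _unopt(rec.get("region_index", "."))
            protein_pos = _unopt(rec.get("protein_pos", "."))
            slot["annotations"].append(
                FunctionalAnnotation(
                    gene_id=gene_id,
                    gene_symbol=_unopt(rec.get("gene_symbol", ".")) or gene_id,
                    transcript=_unopt(rec.get("transcript", ".")) or gene_id,
                    region=Region(rec.get("region", "CDS") or "CDS"),
                    region_index=int(region_index) if region_index else None,
                    func_class=FuncClass(rec.get("func_class") or "NONE"),
                    codon_ref=_unopt(rec.get("codon_ref", ".")),
                    codon_alt=_unopt(rec.get("codon_alt", ".")),
                    aa_ref=_unopt(rec.get("aa_ref", ".")),
                    aa_alt=_unopt(rec.get("aa_alt", ".")),
                    protein_pos=int(protein_pos) if protein_pos else None,
                )
            )
    if n_rows and len(bad_rows) > 0.10 * n_rows:
        raise RowError(
            f"{p.name}: {len(bad_rows)}/{n_rows} rows unparseable: "
            + "; ".join(bad_rows[:5])
        )
    return [
        ObservedVariant(
            key=key,
            individual_id=ind,
            zygosity=slot["zygosity"],
            quality=slot["quality"],
            coverage=slot["coverage"],
            rsid=slot["rsid"],
            annotations=tuple(slot["annotations"]),
        )
        for (key, ind), slot in grouped.items()
    ]


# ---------------------------------------------------------------------------
# CSV export


def export_csv(table, path: str | os.PathLike) -> Path:
    """Write a result table as RFC-4180 CSV (UTF-8, header row).

    Accepts a pandas DataFrame, any object with a ``to_frame()`` method
    (the package's result-table types), or a list of dicts.
    """
    if hasattr(table, "to_frame") and not isinstance(table, pd.DataFrame):
        df = table.to_frame()
    elif isinstance(table, pd.DataFrame):
        df = table
    elif isinstance(table, (list, tuple)):
        df = pd.DataFrame(list(table))
    else:
        raise ConfigError(f"cannot export object of type {type(table).__name__} as CSV")
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(p, index=False, quoting=csv.QUOTE_MINIMAL, encoding="utf-8")
    return p


# ---------------------------------------------------------------------------
# BED12 gene models


def read_gene_models_bed12(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Load toy gene models from BED12 (one transcript per line).

    The BED name field is ``gene_id|transcript|gene_symbol``; blocks are the
    exons and thickStart/thickEnd the CDS bounds.  BED half-open 0-based
    coordinates are converted to the package's closed 1-based convention.
    Returns a mapping transcript -> GeneModel.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"gene model file not found: {p}")
    models: dict[str, GeneModel] = {}
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{p.name}:{lineno}: BED12 needs 12 fields, got {len(f)}")
            chrom_start = int(f[1])
            name_parts = f[3].split("|")
            gene_id = name_parts[0]
            transcript = name_parts[1] if len(name_parts) > 1 else gene_id
            symbol = name_parts[2] if len(name_parts) > 2 else gene_id
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            models[transcript] = GeneModel(
                gene_id=gene_id,
                transcript=transcript,
                gene_symbol=symbol,
                strand=strand,
                exons=exons,
                cds_start=thick_start + 1,
                cds_end=thick_end,
            )
    return models


# ---------------------------------------------------------------------------
# project manifest


@dataclass(frozen=True)
class ManifestEntry:
    individual: Individual
    vcf: Optional[str] = None
    tsv: Optional[str] = None


@dataclass
class Manifest:
    name: str
    genome_build: str
    entries: list[ManifestEntry]
    catalogues: list[dict] = field(default_factory=list)
    gene_models: Optional[str] = None
    base_dir: Path = Path(".")

    def resolve(self, rel: str) -> Path:
        q = Path(rel)
        return q if q.is_absolute() else self.base_dir / q


def read_manifest(path: str | os.PathLike) -> Manifest:
    """Parse the YAML project manifest (individuals, families, file paths)."""
    p = Path(path)
    if not p.exists():
        raise FormatError(f"manifest not found: {p}")
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "individuals" not in doc:
        raise FormatError(f"{p.name}: manifest must be a mapping with an 'individuals' list")
    entries = []
    for item in doc["individuals"]:
        ind = Individual(
            individual_id=str(item["id"]),
            family_id=str(item["family"]) if item.get("family") else None,
            role=Role(str(item.get("role", "OTHER")).upper()),
            affected=bool(item.get("affected", False)),
        )
        entries.append(ManifestEntry(individual=ind, vcf=item.get("vcf"), tsv=item.get("tsv")))
    return Manifest(
        name=str(doc.get("name", p.parent.name)),
        genome_build=str(doc.get("genome_build", "GRCh37")),
        entries=entries,
        catalogues=list(doc.get("catalogues", [])),
        gene_models=doc.get("gene_models"),
        base_dir=p.parent,
    )


def load_project(
    manifest_path: str | os.PathLike, source: str = "vcf"
) -> tuple[Project, dict[str, Catalogue]]:
    """Load a full project (variants + catalogues) from its manifest.

    ``source`` chooses which per-individual file to read ('vcf' or 'tsv');
    both dialects decode to the same observations for files written by the
    cohort simulator.
    """
    if source not in {"vcf", "tsv"}:
        raise ConfigError(f"source must be 'vcf' or 'tsv', got {source!r}")
    man = read_manifest(manifest_path)
    variants: list[ObservedVariant] = []
    for entry in man.entries:
        rel = entry.vcf if source == "vcf" else entry.tsv
        if rel is None:
            raise FormatError(
                f"manifest entry {entry.individual.individual_id} has no {source} file"
            )
        path = man.resolve(rel)
        if source == "vcf":
            variants.extend(read_vcf(path, sample=entry.individual.individual_id))
        else:
            variants.extend(read_annotated_table(path))
    project = Project(
        name=man.name,
        genome_build=man.genome_build,
        individuals=[e.individual for e in man.entries],
        variants=variants,
    )
    catalogues = {
        c["name"]: load_catalogue(man.resolve(c["path"]), c["name"], c.get("match", "either"))
        for c in man.catalogues
    }
    return project, catalogues
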