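"""Synthetic exome cohort generator with known ground truth.

Emits everything a project needs on disk — per-individual variant files in
both supported dialects (VCF and annotated TSV), a known-variant catalogue,
BED12 toy gene models, a YAML manifest and a machine-readable truth file —
so every filter and inheritance strategy is testable without any external
download.

The defaults emulate a multi-individual rare-disease exome study: 14
unrelated affected index cases, ~15,000 variants each, 93.4% of which match
the generated catalogue (so ~6.6% are unknown), laid over toy gene models
(200 genes x 10 exons on chromosomes 1-22/X).  Coordinates only need
internal consistency; no mutation-rate realism, linkage disequilibrium or
sequencing-error model is attempted.

Planted causal variants bypass all stochastic choices: a plant places one
distinct unknown variant of the requested class and zygosity per carrier in
its gene, and planted genes receive no background variants, so recovery of
a plant through the filtering pipeline is deterministic.  Trio members are
generated so that every child background variant is inherited from a
parent; only planted variants can be de novo.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .classify import GENETIC_CODE, classify_snv, translate_codon
from .datamodel import (
    FuncClass,
    FunctionalAnnotation,
    Region,
    VariantKey,
    Zygosity,
    normalize_variant,
)
from .errors import ConfigError
from .io_formats import TSV_COLUMNS, encode_annotation

__all__ = ["Plant", "SimConfig", "SimulatedProject", "simulate", "truth_check", "TruthReport"]

_BASES = "ACGT"

# (codon_ref, position, alt_base) combos of the genetic code, per class —
# sampling from these gives exact control over the functional-class mix.
_SNV_COMBOS: dict[FuncClass, list[tuple[str, int, str]]] = {}
for _codon in GENETIC_CODE:
    for _i in range(3):
        for _b in _BASES:
            if _b == _codon[_i]:
                continue
            _alt_codon = _codon[:_i] + _b + _codon[_i + 1 :]
            _SNV_COMBOS.setdefault(classify_snv(_codon, _alt_codon), []).append(
                (_codon, _i, _b)
            )


@dataclass(frozen=True)
class Plant:
    """A causal variant planted with full ground-truth bookkeeping.

    Each carrier receives its own distinct variant (not a shared allele) in
    ``gene``; planted variants are never entered in the catalogue
    (``known`` stays False, the working assumption for causal variants of a
    rare disorder).
    """

    gene: str
    carriers: tuple[str, ...]
    func_class: FuncClass = FuncClass.MISSENSE
    zygosity: Zygosity = Zygosity.HET
    known: bool = False


@dataclass
class SimConfig:
    """Study conditions of the simulated cohort.

    Defaults mirror a 14-exome unrelated-cases design: ~15,000 variants per
    individual of which ~6.6% are unknown.  ``trios`` lists
    (child, father, mother) id triples; all other individuals are unrelated
    affected index cases.
    """

    seed: int = 0
    n_individuals: int = 14
    n_genes: int = 200
    variants_per_individual: int = 15000
    known_fraction: float = 0.934
    snv_fraction: float = 0.95
    class_mix: dict = field(
        default_factory=lambda: {
            FuncClass.SYNONYMOUS: 0.52,
            FuncClass.MISSENSE: 0.45,
            FuncClass.NONSENSE: 0.02,
            FuncClass.STOP_LOSS: 0.01,
        }
    )
    region_mix: dict = field(
        default_factory=lambda: {
            Region.CDS: 0.78,
            Region.UTR5: 0.04,
            Region.UTR3: 0.06,
            Region.SPLICE_SITE: 0.02,
            Region.INTRON_FLANK: 0.10,
        }
    )
    zygosity_mix: dict = field(
        default_factory=lambda: {Zygosity.HET: 0.8, Zygosity.HOM: 0.2}
    )
    planted: tuple[Plant, ...] = ()
    trios: tuple[tuple[str, str, str], ...] = ()
    name: str = "simulated-cohort"

    @property
    def individual_ids(self) -> list[str]:
        width = max(2, len(str(self.n_individuals)))
        return [f"IND{i:0{width}d}" for i in range(1, self.n_individuals + 1)]

    def validate(self) -> None:
        for label, mix in (
            ("class_mix", self.class_mix),
            ("region_mix", self.region_mix),
            ("zygosity_mix", self.zygosity_mix),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{label} probabilities sum to {total}, expected 1")
        ids = set(self.individual_ids)
        for plant in self.planted:
            missing = set(plant.carriers) - ids
            if missing:
                raise ConfigError(
                    f"plant in {plant.gene} names carriers outside the cohort: {sorted(missing)}"
                )
        for trio in self.trios:
            missing = set(trio) - ids
            if missing:
                raise ConfigError(f"trio {trio} names unknown individuals {sorted(missing)}")
            if len(set(trio)) != 3:
                raise ConfigError(f"trio {trio} must be three distinct individuals")
        if not 0.0 <= self.known_fraction <= 1.0:
            raise ConfigError("known_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# gene model layout

_EXONS_PER_GENE = 10
_EXON_LEN = 150
_INTRON_LEN = 300
_UTR_LEN = 100
_GENE_GAP = 2000
_SIM_CHROMS = [str(i) for i in range(1, 23)] + ["X"]


@dataclass(frozen=True)
class _SimGene:
    gene_id: str
    chrom: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    @property
    def transcript(self) -> str:
        return f"{self.gene_id}.t1"


def _layout_genes(n_genes: int) -> list[_SimGene]:
    genes: list[_SimGene] = []
    next_start: dict[str, int] = {c: 10_001 for c in _SIM_CHROMS}
    for g in range(n_genes):
        chrom = _SIM_CHROMS[g % len(_SIM_CHROMS)]
        start = next_start[chrom]
        exons = []
        pos = start
        for _ in range(_EXONS_PER_GENE):
            exons.append((pos, pos + _EXON_LEN - 1))
            pos += _EXON_LEN + _INTRON_LEN
        next_start[chrom] = exons[-1][1] + _GENE_GAP
        genes.append(
            _SimGene(
                gene_id=f"G{g + 1:04d}",
                chrom=chrom,
                exons=tuple(exons),
                cds_start=exons[0][0] + _UTR_LEN,
                cds_end=exons[-1][1] - _UTR_LEN,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# site generation


@dataclass(frozen=True)
class _Site:
    """A genomic site with its fixed annotation, shareable across individuals."""

    key: VariantKey
    annotation: FunctionalAnnotation
    rsid: Optional[str]


class _SiteFactory:
    def __init__(self, rng: np.random.Generator, config: SimConfig, genes: list[_SimGene]):
        self.rng = rng
        self.config = config
        planted_gene_ids = {p.gene for p in config.planted}
        self.background_genes = [g for g in genes if g.gene_id not in planted_gene_ids]
        if not self.background_genes:
            raise ConfigError("every gene is planted; no room for background variants")
        self.genes_by_id = {g.gene_id: g for g in genes}
        self.used_positions: set[tuple[str, int]] = set()
        self.regions = list(config.region_mix)
        self.region_p = np.array([config.region_mix[r] for r in self.regions])
        self.classes = list(config.class_mix)
        self.class_p = np.array([config.class_mix[c] for c in self.classes])

    def _claim_position(self, gene: _SimGene, sampler) -> int:
        for _ in range(200):
            pos = int(sampler())
            if (gene.chrom, pos) not in self.used_positions:
                self.used_positions.add((gene.chrom, pos))
                return pos
        raise ConfigError(
            f"could not place a variant in {gene.gene_id}: region saturated "
            "(too many variants for too few genes)"
        )

    def _region_position(self, gene: _SimGene, region: Region) -> tuple[int, int]:
        rng = self.rng
        if region is Region.CDS:
            exon_i = int(rng.integers(0, _EXONS_PER_GENE))
            s, e = gene.exons[exon_i]
            s, e = max(s, gene.cds_start), min(e, gene.cds_end)
            return self._claim_position(gene, lambda: rng.integers(s, e + 1)), exon_i + 1
        if region is Region.UTR5:
            s, e = gene.exons[0][0], gene.cds_start - 1
            return self._claim_position(gene, lambda: rng.integers(s, e + 1)), 1
        if region is Region.UTR3:
            s, e = gene.cds_end + 1, gene.exons[-1][1]
            return self._claim_position(gene, lambda: rng.integers(s, e + 1)), _EXONS_PER_GENE
        intron_i = int(rng.integers(0, _EXONS_PER_GENE - 1))
        left_end = gene.exons[intron_i][1]
        right_start = gene.exons[intron_i + 1][0]
        lo, hi = (1, 2) if region is Region.SPLICE_SITE else (3, 20)

        def sampler():
            dist = int(self.rng.integers(lo, hi + 1))
            return left_end + dist if self.rng.random() < 0.5 else right_start - dist

        return self._claim_position(gene, sampler), intron_i + 1

    def _random_base(self, exclude: str = "") -> str:
        choices = [b for b in _BASES if b not in exclude]
        return choices[int(self.rng.integers(0, len(choices)))]

    def make_site(
        self,
        rsid: Optional[str],
        gene: Optional[_SimGene] = None,
        func_class: Optional[FuncClass] = None,
        force_cds_snv: bool = False,
    ) -> _Site:
        rng = self.rng
        if gene is None:
            gene = self.background_genes[int(rng.integers(0, len(self.background_genes)))]
        if force_cds_snv:
            region = Region.CDS
            is_snv = True
        else:
            region = self.regions[int(rng.choice(len(self.regions), p=self.region_p))]
            is_snv = bool(rng.random() < self.config.snv_fraction)
        pos, region_index = self._region_position(gene, region)

        codon_ref = codon_alt = aa_ref = aa_alt = None
        protein_pos = None
        if is_snv:
            if region is Region.CDS:
                fc = func_class
                if fc is None:
                    fc = self.classes[int(rng.choice(len(self.classes), p=self.class_p))]
                combos = _SNV_COMBOS[fc]
                codon_ref, codon_i, alt_base = combos[int(rng.integers(0, len(combos)))]
                ref, alt = codon_ref[codon_i], alt_base
                codon_alt = codon_ref[:codon_i] + alt_base + codon_ref[codon_i + 1 :]
                aa_ref, aa_alt = translate_codon(codon_ref), translate_codon(codon_alt)
                protein_pos = max(1, (pos - gene.cds_start) // 3 + 1)
            else:
                fc = FuncClass.NONE
                ref = self._random_base()
                alt = self._random_base(exclude=ref)
        else:
            anchor = self._random_base()
            length = int(rng.integers(1, 5))
            inserted = "".join(self._random_base() for _ in range(length))
            if rng.random() < 0.5:  # insertion
                ref, alt = anchor, anchor + inserted
            else:  # deletion
                ref, alt = anchor + inserted, anchor
            if region is Region.CDS:
                fc = FuncClass.FRAMESHIFT if length % 3 else FuncClass.NON_FRAMESHIFT
            else:
                fc = FuncClass.NONE

        key = normalize_variant(gene.chrom, pos, ref, alt)
        ann = FunctionalAnnotation(
            gene_id=gene.gene_id,
            gene_symbol=gene.gene_id,
            transcript=gene.transcript,
            region=region,
            region_index=region_index,
            func_class=fc,
            codon_ref=codon_ref,
            codon_alt=codon_alt,
            aa_ref=aa_ref,
            aa_alt=aa_alt,
            protein_pos=protein_pos,
        )
        return _Site(key=key, annotation=ann, rsid=rsid)


# ---------------------------------------------------------------------------
# simulation


@dataclass(frozen=True)
class _Obs:
    site: _Site
    zygosity: Zygosity
    quality: float
    coverage: int
    planted: bool = False


@dataclass
class SimulatedProject:
    """Paths and ground truth of a generated cohort."""

    directory: Path
    manifest_path: Path
    truth_path: Path
    catalogue_path: Path
    gene_models_path: Path
    truth: dict


def simulate(config: SimConfig, outdir: str | Path) -> SimulatedProject:
    """Generate a cohort on disk; byte-identical for identical (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    (outdir / "tsv").mkdir(parents=True, exist_ok=True)
    (outdir / "catalogues").mkdir(parents=True, exist_ok=True)

    genes = _layout_genes(config.n_genes)
    factory = _SiteFactory(rng, config, genes)
    ids = config.individual_ids

    # shared pool of catalogued sites; sized so individuals overlap heavily
    pool_size = max(1, int(config.variants_per_individual * 1.5))
    known_pool = [factory.make_site(rsid=f"rs{1_000_001 + i}") for i in range(pool_size)]

    trio_children = {t[0]: (t[1], t[2]) for t in config.trios}
    trio_parents = {p for t in config.trios for p in t[1:]}

    def draw_zygosity() -> Zygosity:
        return (
            Zygosity.HET
            if rng.random() < config.zygosity_mix[Zygosity.HET]
            else Zygosity.HOM
        )

    def draw_observation(site: _Site, zygosity: Optional[Zygosity] = None, planted=False) -> _Obs:
        return _Obs(
            site=site,
            zygosity=zygosity or draw_zygosity(),
            quality=round(float(rng.uniform(20.0, 60.0)), 1),
            coverage=int(rng.poisson(65)),
            planted=planted,
        )

    observations: dict[str, list[_Obs]] = {i: [] for i in ids}
    novel_counter = 0

    def background_for(individual: str) -> None:
        nonlocal novel_counter
        n = int(rng.poisson(config.variants_per_individual))
        n_known = int(rng.binomial(n, config.known_fraction))
        pool_idx = rng.choice(pool_size, size=min(n_known, pool_size), replace=False)
        for i in sorted(int(j) for j in pool_idx):
            observations[individual].append(draw_observation(known_pool[i]))
        for _ in range(n - n_known):
            novel_counter += 1
            observations[individual].append(draw_observation(factory.make_site(rsid=None)))

    # parents and unrelated individuals get independent backgrounds; trio
    # children inherit their background from the parents so that only
    # planted variants can be de novo
    for individual in ids:
        if individual not in trio_children:
            background_for(individual)
    for child, (father, mother) in trio_children.items():
        inherited: dict = {}  # key -> (site, n transmitting parents)
        for parent in (father, mother):
            parent_obs = observations[parent]
            take = rng.random(len(parent_obs)) < 0.5
            for obs, t in zip(parent_obs, take):
                if t:
                    prev = inherited.get(obs.site.key)
                    inherited[obs.site.key] = (obs.site, (prev[1] if prev else 0) + 1)
        for site, n_parents in inherited.values():
            observations[child].append(
                _Obs(
                    site=site,
                    zygosity=Zygosity.HOM if n_parents == 2 else Zygosity.HET,
                    quality=round(float(rng.uniform(20.0, 60.0)), 1),
                    coverage=int(rng.poisson(65)),
                )
            )

    planted_truth = []
    for plant in config.planted:
        gene = factory.genes_by_id.get(plant.gene)
        if gene is None:
            raise ConfigError(f"planted gene {plant.gene!r} not in the gene models")
        carrier_keys = {}
        for carrier in plant.carriers:
            site = factory.make_site(
                rsid=None, gene=gene, func_class=plant.func_class, force_cds_snv=True
            )
            observations[carrier].append(
                draw_observation(site, zygosity=plant.zygosity, planted=True)
            )
            carrier_keys[carrier] = str(site.key)
        planted_truth.append(
            {
                "gene": plant.gene,
                "carriers": list(plant.carriers),
                "func_class": plant.func_class.value,
                "zygosity": plant.zygosity.value,
                "known": plant.known,
                "keys": carrier_keys,
            }
        )

    for individual in ids:
        observations[individual].sort(
            key=lambda o: (_SIM_CHROMS.index(o.site.key.chrom), o.site.key.pos, o.site.key.alt)
        )

    # --- write outputs -----------------------------------------------------
    gene_models_path = outdir / "genes.bed"
    _write_bed12(gene_models_path, genes)
    catalogue_path = outdir / "catalogues" / "known.vcf"
    _write_catalogue_vcf(catalogue_path, known_pool, genes)
    for individual in ids:
        _write_sample_vcf(outdir / "vcf" / f"{individual}.vcf", individual, observations[individual], genes)
        _write_sample_tsv(outdir / "tsv" / f"{individual}.tsv", individual, observations[individual])

    manifest_path = outdir / "manifest.yaml"
    manifest = {
        "name": config.name,
        "genome_build": "toybuild-1",
        "gene_models": "genes.bed",
        "catalogues": [{"name": "known", "path": "catalogues/known.vcf", "match": "either"}],
        "individuals": [],
    }
    family_of = {}
    role_of = {}
    for i, (child, father, mother) in enumerate(config.trios, start=1):
        fam = f"F{i:02d}"
        family_of.update({child: fam, father: fam, mother: fam})
        role_of.update({child: "INDEX", father: "FATHER", mother: "MOTHER"})
    for individual in ids:
        manifest["individuals"].append(
            {
                "id": individual,
                "family": family_of.get(individual),
                "role": role_of.get(individual, "INDEX"),
                "affected": role_of.get(individual, "INDEX") == "INDEX",
                "vcf": f"vcf/{individual}.vcf",
                "tsv": f"tsv/{individual}.tsv",
            }
        )
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    truth = {
        "project": config.name,
        "seed": config.seed,
        "n_individuals": config.n_individuals,
        "planted_genes": sorted({p["gene"] for p in planted_truth}),
        "planted": planted_truth,
        "individuals": {
            individual: {
                "n_variants": len(obs),
                "n_known": sum(1 for o in obs if o.site.rsid is not None),
                "n_unknown": sum(1 for o in obs if o.site.rsid is None),
                "variants": [
                    {
                        "key": str(o.site.key),
                        "known": o.site.rsid is not None,
                        "gene": o.site.annotation.gene_id,
                        "region": o.site.annotation.region.value,
                        "func_class": o.site.annotation.func_class.value,
                        "zygosity": o.zygosity.value,
                        "planted": o.planted,
                    }
                    for o in obs
                ],
            }
            for individual, obs in observations.items()
        },
    }
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=False)

    return SimulatedProject(
        directory=outdir,
        manifest_path=manifest_path,
        truth_path=truth_path,
        catalogue_path=catalogue_path,
        gene_models_path=gene_models_path,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# writers (plain text, no timestamps, deterministic ordering)


def _contig_lines(genes: list[_SimGene]) -> list[str]:
    maxpos: dict[str, int] = {}
    for g in genes:
        maxpos[g.chrom] = max(maxpos.get(g.chrom, 0), g.exons[-1][1] + _GENE_GAP)
    return [
        f"##contig=<ID={c},length={maxpos[c]}>"
        for c in _SIM_CHROMS
        if c in maxpos
    ]


def _vcf_header(genes: list[_SimGene], sample: Optional[str]) -> list[str]:
    lines = ["##fileformat=VCFv4.2", *_contig_lines(genes)]
    lines.append(
        '##INFO=<ID=TXA,Number=.,Type=String,Description="Transcript annotation: '
        "allele|gene_id|gene_symbol|transcript|region|region_index|func_class|"
        'codon_ref|codon_alt|aa_ref|aa_alt|protein_pos">'
    )
    if sample is not None:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
        )
    else:
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return lines


def _write_sample_vcf(path: Path, individual: str, obs: list[_Obs], genes: list[_SimGene]) -> None:
    lines = _vcf_header(genes, sample=individual)
    for o in obs:
        k = o.site.key
        txa = encode_annotation(k.alt, o.site.annotation)
        gt = "0/1" if o.zygosity is Zygosity.HET else "1/1"
        lines.append(
            "\t".join(
                [
                    k.chrom,
                    str(k.pos),
                    o.site.rsid or ".",
                    k.ref,
                    k.alt,
                    f"{o.quality:.1f}",
                    "PASS",
                    f"TXA={txa}",
                    "GT:DP",
                    f"{gt}:{o.coverage}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_catalogue_vcf(path: Path, sites: list[_Site], genes: list[_SimGene]) -> None:
    ordered = sorted(sites, key=lambda s: (_SIM_CHROMS.index(s.key.chrom), s.key.pos, s.key.alt))
    lines = _vcf_header(genes, sample=None)
    for s in ordered:
        k = s.key
        lines.append(
            "\t".join([k.chrom, str(k.pos), s.rsid or ".", k.ref, k.alt, ".", ".", "."])
        )
    path.write_text("\n".join(lines) + "\n")


def _write_sample_tsv(path: Path, individual: str, obs: list[_Obs]) -> None:
    def opt(v) -> str:
        return "." if v is None else str(v)

    rows = ["\t".join(TSV_COLUMNS)]
    for o in obs:
        k, a = o.site.key, o.site.annotation
        rows.append(
            "\t".join(
                [
                    individual,
                    k.chrom,
                    str(k.pos),
                    k.ref,
                    k.alt,
                    "het" if o.zygosity is Zygosity.HET else "hom",
                    f"{o.quality:.1f}",
                    str(o.coverage),
                    opt(o.site.rsid),
                    a.gene_id,
                    opt(a.gene_symbol),
                    a.transcript,
                    a.region.value,
                    opt(a.region_index),
                    a.func_class.value,
                    opt(a.codon_ref),
                    opt(a.codon_alt),
                    opt(a.aa_ref),
                    opt(a.aa_alt),
                    opt(a.protein_pos),
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n")


def _write_bed12(path: Path, genes: list[_SimGene]) -> None:
    lines = []
    for g in genes:
        chrom_start = g.exons[0][0] - 1
        chrom_end = g.exons[-1][1]
        sizes = ",".join(str(e - s + 1) for s, e in g.exons)
        starts = ",".join(str(s - 1 - chrom_start) for s, _ in g.exons)
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    str(chrom_start),
                    str(chrom_end),
                    f"{g.gene_id}|{g.transcript}|{g.gene_id}",
                    "0",
                    "+",
                    str(g.cds_start - 1),
                    str(g.cds_end),
                    "0",
                    str(len(g.exons)),
                    sizes,
                    starts,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# truth checking


@dataclass
class TruthReport:
    exact_match: bool
    misses: list[str]
    spurious: list[str]

    def to_frame(self):
        import pandas as pd

        rows = [{"kind": "miss", "gene": g} for g in self.misses] + [
            {"kind": "spurious", "gene": g} for g in self.spurious
        ]
        return pd.DataFrame(rows, columns=["kind", "gene"])


def truth_check(project_results: Mapping, truth: Mapping | str | Path) -> TruthReport:
    """Compare recovered causal genes against the simulator's truth file.

    ``project_results`` is a mapping with keys ``project`` (name, checked
    against the truth file) and ``genes`` (the recovered causal gene list).
    Misses are planted genes not recovered; spurious entries are recovered
    genes never planted.
    """
    if not isinstance(truth, Mapping):
        with open(truth) as fh:
            truth = json.load(fh)
    if project_results.get("project") != truth.get("project"):
        raise ConfigError(
            f"results are for project {project_results.get('project')!r} but the truth "
            f"file describes {truth.get('project')!r}"
        )
    recovered = set(project_results.get("genes", ()))
    planted = set(truth.get("planted_genes", ()))
    misses = sorted(planted - recovered)
    spurious = sorted(recovered - planted)
    return TruthReport(exact_match=not misses and not spurious, misses=misses, spurious=spurious)


def sha256_of_tree(directory: str | Path) -> str:
    """Single digest over every file (path + content) under a directory."""
    h = hashlib.sha256()
    for path in sorted(Path(directory).rglob("*")):
        if path.is_file():
            h.update(str(path.relative_to(directory)).encode())
            h.update(path.read_bytes())
    return h.hexdigest()
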