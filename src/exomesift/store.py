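"""Embedded relational project store (SQLite).

The store mirrors the package's in-memory model in four content tables —
individual, variation, observation (one row per variant x individual) and
annotation (one row per transcript annotation) — plus catalogue tables, so
filter recipes can be compiled into a single parameterized SQL query
(:meth:`ProjectStore.query_recipe`).  The in-memory path
(:func:`exomesift.filters.apply_recipe`) computes the same result without a
database; both are kept and cross-checked in the test suite.

Loading is idempotent: re-loading the same project replaces content
wholesale, so identical inputs yield identical stores.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .datamodel import (
    FuncClass,
    FunctionalAnnotation,
    Individual,
    ObservedVariant,
    Project,
    Region,
    Role,
    VariantKey,
    VariantType,
    Zygosity,
    chrom_sort_key,
)
from .errors import ConfigError, StoreError
from .filters import FilterRecipe
from .io_formats import Catalogue

__all__ = ["ProjectStore", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS individual (
    individual_id TEXT PRIMARY KEY,
    family_id TEXT,
    role TEXT NOT NULL,
    affected INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS variation (
    variation_id INTEGER PRIMARY KEY,
    chrom TEXT NOT NULL,
    chrom_order INTEGER NOT NULL,
    pos INTEGER NOT NULL,
    ref TEXT NOT NULL,
    alt TEXT NOT NULL,
    vtype TEXT NOT NULL,
    UNIQUE (chrom, pos, ref, alt)
);
CREATE TABLE IF NOT EXISTS observation (
    variation_id INTEGER NOT NULL REFERENCES variation,
    individual_id TEXT NOT NULL REFERENCES individual,
    zygosity TEXT NOT NULL,
    quality REAL NOT NULL,
    coverage INTEGER NOT NULL,
    rsid TEXT,
    filter_flag TEXT,
    PRIMARY KEY (variation_id, individual_id)
);
CREATE TABLE IF NOT EXISTS annotation (
    variation_id INTEGER NOT NULL,
    individual_id TEXT NOT NULL,
    ann_index INTEGER NOT NULL,
    gene_id TEXT NOT NULL,
    gene_symbol TEXT,
    transcript TEXT NOT NULL,
    region TEXT NOT NULL,
    region_index INTEGER,
    func_class TEXT NOT NULL,
    codon_ref TEXT,
    codon_alt TEXT,
    aa_ref TEXT,
    aa_alt TEXT,
    protein_pos INTEGER,
    PRIMARY KEY (variation_id, individual_id, ann_index)
);
CREATE TABLE IF NOT EXISTS catalogue_meta (
    catalogue TEXT PRIMARY KEY,
    match_policy TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS catalogue_key (
    catalogue TEXT NOT NULL,
    chrom TEXT NOT NULL,
    pos INTEGER NOT NULL,
    ref TEXT NOT NULL,
    alt TEXT NOT NULL,
    PRIMARY KEY (catalogue, chrom, pos, ref, alt)
);
CREATE TABLE IF NOT EXISTS catalogue_rsid (
    catalogue TEXT NOT NULL,
    rsid TEXT NOT NULL,
    PRIMARY KEY (catalogue, rsid)
);
CREATE INDEX IF NOT EXISTS idx_annotation_gene ON annotation (gene_id);
CREATE INDEX IF NOT EXISTS idx_observation_ind ON observation (individual_id);
"""


class ProjectStore:
    """One project per SQLite file; schema version recorded and checked."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.conn = sqlite3.connect(str(self.path))
        self.conn.executescript(_SCHEMA)
        row = self.conn.execute(
            "SELECT value FROM meta WHERE key = 'schema_version'"
        ).fetchone()
        if row is None:
            self.conn.execute(
                "INSERT INTO meta (key, value) VALUES ('schema_version', ?)",
                (SCHEMA_VERSION,),
            )
            self.conn.commit()
        elif row[0] != SCHEMA_VERSION:
            raise StoreError(
                f"store {self.path} has schema version {row[0]}, "
                f"this build expects {SCHEMA_VERSION}"
            )

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "ProjectStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- loading -----------------------------------------------------------

    def load_project(
        self, project: Project, catalogues: Optional[Mapping[str, Catalogue]] = None
    ) -> dict:
        """Replace store content with a project; returns an ingest report."""
        cur = self.conn.cursor()
        for table in (
            "annotation",
            "observation",
            "variation",
            "individual",
            "catalogue_key",
            "catalogue_rsid",
            "catalogue_meta",
        ):
            cur.execute(f"DELETE FROM {table}")
        cur.execute(
            "INSERT OR REPLACE INTO meta (key, value) VALUES ('project_name', ?)",
            (project.name,),
        )
        cur.execute(
            "INSERT OR REPLACE INTO meta (key, value) VALUES ('genome_build', ?)",
            (project.genome_build,),
        )
        for ind in project.individuals:
            cur.execute(
                "INSERT INTO individual VALUES (?, ?, ?, ?)",
                (ind.individual_id, ind.family_id, ind.role.value, int(ind.affected)),
            )

        var_ids: dict[VariantKey, int] = {}
        n_obs = 0
        for v in project.variants:
            key = v.key
            if key not in var_ids:
                cur.execute(
                    "INSERT INTO variation (chrom, chrom_order, pos, ref, alt, vtype) "
                    "VALUES (?, ?, ?, ?, ?, ?)",
                    (key.chrom, chrom_sort_key(key.chrom), key.pos, key.ref, key.alt,
                     key.vtype.value),
                )
                var_ids[key] = cur.lastrowid
            vid = var_ids[key]
            try:
                cur.execute(
                    "INSERT INTO observation VALUES (?, ?, ?, ?, ?, ?, ?)",
                    (vid, v.individual_id, v.zygosity.value, v.quality, v.coverage,
                     v.rsid, v.filter_flag),
                )
            except sqlite3.IntegrityError as exc:
                raise StoreError(
                    f"duplicate observation of {key} for {v.individual_id}"
                ) from exc
            n_obs += 1
            for i, a in enumerate(v.annotations):
                cur.execute(
                    "INSERT INTO annotation VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                    (vid, v.individual_id, i, a.gene_id, a.gene_symbol, a.transcript,
                     a.region.value, a.region_index, a.func_class.value,
                     a.codon_ref, a.codon_alt, a.aa_ref, a.aa_alt, a.protein_pos),
                )
        for cat in (catalogues or {}).values():
            cur.execute(
                "INSERT INTO catalogue_meta VALUES (?, ?)", (cat.name, cat.match)
            )
            for k in sorted(cat.keys):
                cur.execute(
                    "INSERT INTO catalogue_key VALUES (?, ?, ?, ?, ?)",
                    (cat.name, k.chrom, k.pos, k.ref, k.alt),
                )
            for rsid in sorted(cat.rsids):
                cur.execute("INSERT INTO catalogue_rsid VALUES (?, ?)", (cat.name, rsid))
        self.conn.commit()
        return {
            "individuals": len(project.individuals),
            "variants": len(var_ids),
            "observations": n_obs,
            "catalogues": len(catalogues or {}),
        }

    # -- reading back --------------------------------------------------------

    def _annotations_for(self, vid: int, individual_id: str) -> tuple[FunctionalAnnotation, ...]:
        rows = self.conn.execute(
            "SELECT gene_id, gene_symbol, transcript, region, region_index, func_class, "
            "codon_ref, codon_alt, aa_ref, aa_alt, protein_pos FROM annotation "
            "WHERE variation_id = ? AND individual_id = ? ORDER BY ann_index",
            (vid, individual_id),
        ).fetchall()
        return tuple(
            FunctionalAnnotation(
                gene_id=r[0],
                gene_symbol=r[1] or r[0],
                transcript=r[2],
                region=Region(r[3]),
                region_index=r[4],
                func_class=FuncClass(r[5]),
                codon_ref=r[6],
                codon_alt=r[7],
                aa_ref=r[8],
                aa_alt=r[9],
                protein_pos=r[10],
            )
            for r in rows
        )

    def _observed(self, row) -> ObservedVariant:
        (vid, chrom, pos, ref, alt, vtype, individual_id, zygosity, quality,
         coverage, rsid, filter_flag) = row
        return ObservedVariant(
            key=VariantKey(chrom, pos, ref, alt, VariantType(vtype)),
            individual_id=individual_id,
            zygosity=Zygosity(zygosity),
            quality=quality,
            coverage=coverage,
            rsid=rsid,
            annotations=self._annotations_for(vid, individual_id),
            filter_flag=filter_flag,
        )

    _OBS_SELECT = (
        "SELECT v.variation_id, v.chrom, v.pos, v.ref, v.alt, v.vtype, "
        "o.individual_id, o.zygosity, o.quality, o.coverage, o.rsid, o.filter_flag "
        "FROM observation o JOIN variation v ON v.variation_id = o.variation_id "
    )
    _OBS_ORDER = " ORDER BY v.chrom_order, v.pos, v.ref, v.alt, o.individual_id"

    def meta(self, key: str) -> Optional[str]:
        row = self.conn.execute("SELECT value FROM meta WHERE key = ?", (key,)).fetchone()
        return row[0] if row else None

    def individuals(self) -> list[Individual]:
        rows = self.conn.execute(
            "SELECT individual_id, family_id, role, affected FROM individual "
            "ORDER BY rowid"
        ).fetchall()
        return [Individual(r[0], r[1], Role(r[2]), bool(r[3])) for r in rows]

    def catalogues(self) -> dict[str, Catalogue]:
        out: dict[str, Catalogue] = {}
        for name, policy in self.conn.execute(
            "SELECT catalogue, match_policy FROM catalogue_meta ORDER BY catalogue"
        ):
            keys = frozenset(
                VariantKey(
                    c, p, r, a,
                    VariantType.SNV if len(r) == len(a) == 1
                    else (VariantType.INSERTION if len(a) > len(r) else VariantType.DELETION),
                )
                for c, p, r, a in self.conn.execute(
                    "SELECT chrom, pos, ref, alt FROM catalogue_key WHERE catalogue = ?",
                    (name,),
                )
            )
            rsids = frozenset(
                r[0]
                for r in self.conn.execute(
                    "SELECT rsid FROM catalogue_rsid WHERE catalogue = ?", (name,)
                )
            )
            out[name] = Catalogue(name=name, keys=keys, rsids=rsids, match=policy)
        return out

    def to_project(self) -> Project:
        rows = self.conn.execute(self._OBS_SELECT + self._OBS_ORDER).fetchall()
        return Project(
            name=self.meta("project_name") or self.path.stem,
            genome_build=self.meta("genome_build") or "unknown",
            individuals=self.individuals(),
            variants=[self._observed(r) for r in rows],
        )

    # -- queries -------------------------------------------------------------

    def search(self, query: str) -> list[ObservedVariant]:
        """Direct lookup: 'GENE:<id>', 'rs<number>' or 'chrom:start-end'."""
        query = query.strip()
        if query.upper().startswith("GENE:"):
            gene = query.split(":", 1)[1]
            sql = self._OBS_SELECT + (
                "WHERE EXISTS (SELECT 1 FROM annotation a WHERE "
                "a.variation_id = o.variation_id AND a.individual_id = o.individual_id "
                "AND a.gene_id = ?)"
            ) + self._OBS_ORDER
            rows = self.conn.execute(sql, (gene,)).fetchall()
        elif query.startswith("rs"):
            rows = self.conn.execute(
                self._OBS_SELECT + "WHERE o.rsid = ?" + self._OBS_ORDER, (query,)
            ).fetchall()
        else:
            try:
                chrom, span = query.split(":")
                start_s, end_s = span.split("-")
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ConfigError(
                    f"unparseable query {query!r}; expected GENE:<id>, rs<number> "
                    "or chrom:start-end"
                ) from exc
            rows = self.conn.execute(
                self._OBS_SELECT + "WHERE v.chrom = ? AND v.pos BETWEEN ? AND ?"
                + self._OBS_ORDER,
                (chrom.removeprefix("chr"), start, end),
            ).fetchall()
        return [self._observed(r) for r in rows]

    def query_recipe(self, recipe: FilterRecipe) -> list[ObservedVariant]:
        """Compile a filter recipe into one parameterized SQL query.

        Semantics are identical to :func:`exomesift.filters.apply_recipe`
        on the same content (verified by the test suite).
        """
        clauses: list[str] = []
        params: list = []
        if recipe.individuals:
            known = {i.individual_id for i in self.individuals()}
            unknown = recipe.individuals - known
            if unknown:
                raise ConfigError(f"recipe names unknown individual(s) {sorted(unknown)}")
            ph = ",".join("?" * len(recipe.individuals))
            clauses.append(f"o.individual_id IN ({ph})")
            params.extend(sorted(recipe.individuals))
        if recipe.zygosity is not None:
            clauses.append("o.zygosity = ?")
            params.append(recipe.zygosity.value)
        if recipe.min_quality is not None:
            clauses.append("o.quality >= ?")
            params.append(recipe.min_quality)
        if recipe.min_coverage is not None:
            clauses.append("o.coverage >= ?")
            params.append(recipe.min_coverage)
        if recipe.genomic_interval is not None:
            c, s, e = recipe.genomic_interval
            clauses.append("v.chrom = ? AND v.pos BETWEEN ? AND ?")
            params.extend([c, s, e])
        stored = {
            name: policy
            for name, policy in self.conn.execute(
                "SELECT catalogue, match_policy FROM catalogue_meta"
            )
        }
        for name in recipe.exclude_catalogues:
            if name not in stored:
                raise ConfigError(f"recipe names unknown catalogue {name!r}")
            key_exists = (
                "EXISTS (SELECT 1 FROM catalogue_key ck WHERE ck.catalogue = ? "
                "AND ck.chrom = v.chrom AND ck.pos = v.pos AND ck.ref = v.ref "
                "AND ck.alt = v.alt)"
            )
            rsid_exists = (
                "(o.rsid IS NOT NULL AND EXISTS (SELECT 1 FROM catalogue_rsid cr "
                "WHERE cr.catalogue = ? AND cr.rsid = o.rsid))"
            )
            policy = stored[name]
            if policy == "key":
                clauses.append(f"NOT {key_exists}")
                params.append(name)
            elif policy == "rsid":
                clauses.append(f"NOT {rsid_exists}")
                params.append(name)
            else:
                clauses.append(f"NOT ({key_exists} OR {rsid_exists})")
                params.extend([name, name])
        if recipe.genes:
            ph = ",".join("?" * len(recipe.genes))
            clauses.append(
                "EXISTS (SELECT 1 FROM annotation a WHERE a.variation_id = o.variation_id "
                f"AND a.individual_id = o.individual_id AND a.gene_id IN ({ph}))"
            )
            params.extend(sorted(recipe.genes))
        if recipe.include_regions or recipe.include_func_classes:
            conds = []
            sub_params: list = []
            if recipe.include_regions:
                ph = ",".join("?" * len(recipe.include_regions))
                conds.append(f"a.region IN ({ph})")
                sub_params.extend(sorted(r.value for r in recipe.include_regions))
            if recipe.include_func_classes:
                ph = ",".join("?" * len(recipe.include_func_classes))
                conds.append(f"a.func_class IN ({ph})")
                sub_params.extend(sorted(c.value for c in recipe.include_func_classes))
            cond = " AND ".join(conds)
            has_ann = (
                "EXISTS (SELECT 1 FROM annotation a WHERE a.variation_id = o.variation_id "
                "AND a.individual_id = o.individual_id)"
            )
            if recipe.annotation_match == "any":
                clauses.append(
                    "EXISTS (SELECT 1 FROM annotation a WHERE "
                    "a.variation_id = o.variation_id AND a.individual_id = o.individual_id "
                    f"AND {cond})"
                )
                params.extend(sub_params)
            else:
                clauses.append(
                    f"{has_ann} AND NOT EXISTS (SELECT 1 FROM annotation a WHERE "
                    "a.variation_id = o.variation_id AND a.individual_id = o.individual_id "
                    f"AND NOT ({cond}))"
                )
                params.extend(sub_params)
        sql = self._OBS_SELECT
        if clauses:
            sql += "WHERE " + " AND ".join(f"({c})" for c in clauses)
        sql += self._OBS_ORDER
        return [self._observed(r) for r in self.conn.execute(sql, params).fetchall()]
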