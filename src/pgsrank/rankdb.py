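"""SQLite materialization of trait-specific variant and gene rankings.

The database is a single SQLite file with five tables::

    traits(trait)
    scores(pgs_id, trait, n_variants)
    variant_ranks(trait, variant_key, mrr, n_present, n_pgs)
    gene_ranks(trait, gene, score, n_variants, best_variant)
    summary(trait, n_files, w_min, w_max, mean, median, sd, n_rows)

Referential integrity and uniqueness are enforced by schema constraints;
``PRAGMA user_version`` carries the schema version.  Builds are atomic
(write to a temporary file, move into place on success), so a failed build
never leaves a partial database behind.  Query results are pure functions
of the file: repeated queries return identical rows.

Trait names are stored verbatim but matched case-insensitively with a
substring fallback, so the query term "Alzheimer" finds the stored trait
"Alzheimer's disease".
"""

from __future__ import annotations

import logging
import os
import sqlite3
from pathlib import Path
from typing import Iterable, Sequence

from .annotate import GeneRankRecord
from .harmonize import TraitDataset
from .rank_aggregate import VariantRankRecord
from .trait_stats import SummaryStats

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE traits (
    trait TEXT PRIMARY KEY
);
CREATE TABLE scores (
    pgs_id TEXT NOT NULL,
    trait TEXT NOT NULL REFERENCES traits(trait),
    n_variants INTEGER NOT NULL,
    PRIMARY KEY (pgs_id, trait)
);
CREATE TABLE variant_ranks (
    trait TEXT NOT NULL REFERENCES traits(trait),
    variant_key TEXT NOT NULL,
    mrr REAL NOT NULL,
    n_present INTEGER NOT NULL,
    n_pgs INTEGER NOT NULL,
    PRIMARY KEY (trait, variant_key)
);
CREATE TABLE gene_ranks (
    trait TEXT NOT NULL REFERENCES traits(trait),
    gene TEXT NOT NULL,
    score REAL NOT NULL,
    n_variants INTEGER NOT NULL,
    best_variant TEXT NOT NULL,
    PRIMARY KEY (trait, gene)
);
CREATE TABLE summary (
    trait TEXT PRIMARY KEY REFERENCES traits(trait),
    n_files INTEGER NOT NULL,
    w_min REAL NOT NULL,
    w_max REAL NOT NULL,
    mean REAL NOT NULL,
    median REAL NOT NULL,
    sd REAL NOT NULL,
    n_rows INTEGER NOT NULL
);
"""


class RankDatabaseError(ValueError):
    """Database construction or query violated a contract."""


class UnknownTraitError(RankDatabaseError):
    """Query named a trait that matches nothing in the database."""

    def __init__(self, trait: str, available: Sequence[str]):
        self.trait = trait
        self.available = list(available)
        super().__init__(
            f"unknown trait {trait!r}; available traits: {', '.join(available) or '(none)'}"
        )


def build_db(
    datasets: Sequence[TraitDataset],
    ranks: Sequence[VariantRankRecord],
    gene_ranks: Sequence[GeneRankRecord] = (),
    summaries: Sequence[SummaryStats] = (),
    path: str | Path = "pgsrank.db",
    overwrite: bool = False,
) -> "RankDatabase":
    """Materialize datasets, ranks, rollups and summaries into one file.

    The build is atomic: everything is written to ``<path>.tmp`` and moved
    into place only after all rows insert cleanly; a constraint violation
    aborts the build and removes the temporary file.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise RankDatabaseError(f"{path} exists (pass overwrite=True to replace)")
    tmp = path.with_name(path.name + ".tmp")
    if tmp.exists():
        tmp.unlink()
    conn = sqlite3.connect(tmp)
    try:
        conn.execute("PRAGMA foreign_keys = ON")
        conn.executescript(_SCHEMA)
        conn.execute(f"PRAGMA user_version = {SCHEMA_VERSION}")
        conn.executemany(
            "INSERT INTO traits VALUES (?)", [(ds.trait,) for ds in datasets]
        )
        score_rows = []
        for ds in datasets:
            for sf in ds.files:
                score_rows.append((sf.pgs_id, ds.trait, len(sf.records)))
        conn.executemany("INSERT INTO scores VALUES (?,?,?)", score_rows)
        conn.executemany(
            "INSERT INTO variant_ranks VALUES (?,?,?,?,?)",
            [(r.trait, r.variant_key, r.mrr, r.n_present, r.n_pgs) for r in ranks],
        )
        conn.executemany(
            "INSERT INTO gene_ranks VALUES (?,?,?,?,?)",
            [(g.trait, g.gene, g.score, g.n_variants, g.best_variant) for g in gene_ranks],
        )
        conn.executemany(
            "INSERT INTO summary VALUES (?,?,?,?,?,?,?,?)",
            [
                (s.trait, s.n_files, s.w_min, s.w_max, s.mean, s.median, s.sd, s.n_rows)
                for s in summaries
            ],
        )
        conn.commit()
    except sqlite3.IntegrityError as exc:
        conn.close()
        tmp.unlink(missing_ok=True)
        raise RankDatabaseError(f"constraint violation during build: {exc}") from exc
    conn.close()
    if path.exists():
        path.unlink()
    os.replace(tmp, path)
    logger.info("built rank database %s (%d traits, %d variant ranks)", path, len(datasets), len(ranks))
    return RankDatabase(path)


class RankDatabase:
    """Read-only handle over a built rank database file."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if not self.path.exists():
            raise RankDatabaseError(f"database file {self.path} does not exist")

    def _connect(self) -> sqlite3.Connection:
        conn = sqlite3.connect(f"file:{self.path}?mode=ro", uri=True)
        conn.execute("PRAGMA foreign_keys = ON")
        return conn

    @property
    def schema_version(self) -> int:
        with self._connect() as conn:
            return int(conn.execute("PRAGMA user_version").fetchone()[0])

    def traits(self) -> list[str]:
        with self._connect() as conn:
            return [row[0] for row in conn.execute("SELECT trait FROM traits ORDER BY trait")]

    def resolve_trait(self, trait: str) -> str:
        """Map a query term to a stored trait name.

        Exact case-insensitive match first, then case-insensitive substring
        ("Alzheimer" → "Alzheimer's disease").  Ambiguous substring matches
        and misses both raise :class:`UnknownTraitError`.
        """
        stored = self.traits()
        exact = [t for t in stored if t.lower() == trait.lower()]
        if exact:
            return exact[0]
        partial = [t for t in stored if trait.lower() in t.lower()]
        if len(partial) == 1:
            return partial[0]
        if len(partial) > 1:
            raise UnknownTraitError(f"{trait} (ambiguous: {partial})", stored)
        raise UnknownTraitError(trait, stored)

    def query_top_variants(self, trait: str, n: int) -> list[VariantRankRecord]:
        """Top ``n`` variants by MRR descending, variant key ascending."""
        if n < 1:
            raise RankDatabaseError("n must be >= 1")
        resolved = self.resolve_trait(trait)
        with self._connect() as conn:
            rows = conn.execute(
                "SELECT trait, variant_key, mrr, n_present, n_pgs FROM variant_ranks "
                "WHERE trait = ? ORDER BY mrr DESC, variant_key ASC LIMIT ?",
                (resolved, n),
            ).fetchall()
        return [VariantRankRecord(*row) for row in rows]

    def query_top_genes(self, trait: str, n: int) -> list[GeneRankRecord]:
        """Top ``n`` genes by score descending, gene ascending (each gene once)."""
        if n < 1:
            raise RankDatabaseError("n must be >= 1")
        resolved = self.resolve_trait(trait)
        with self._connect() as conn:
            rows = conn.execute(
                "SELECT trait, gene, score, n_variants, best_variant FROM gene_ranks "
                "WHERE trait = ? ORDER BY score DESC, gene ASC LIMIT ?",
                (resolved, n),
            ).fetchall()
        return [GeneRankRecord(*row) for row in rows]

    def summaries(self, trait: str | None = None) -> list[SummaryStats]:
        sql = "SELECT trait, n_files, w_min, w_max, mean, median, sd, n_rows FROM summary"
        args: tuple = ()
        if trait is not None:
            sql += " WHERE trait = ?"
            args = (self.resolve_trait(trait),)
        sql += " ORDER BY trait"
        with self._connect() as conn:
            rows = conn.execute(sql, args).fetchall()
        return [SummaryStats(*row) for row in rows]

    def integrity_check(self) -> list[str]:
        """Verify referential integrity and uniqueness over all tables.

        Returns a list of violation descriptions; an empty list means the
        database is consistent.
        """
        problems: list[str] = []
        with self._connect() as conn:
            for table in ("scores", "variant_ranks", "gene_ranks", "summary"):
                orphans = conn.execute(
                    f"SELECT COUNT(*) FROM {table} t "
                    "LEFT JOIN traits USING (trait) WHERE traits.trait IS NULL"
                ).fetchone()[0]
                if orphans:
                    problems.append(f"{table}: {orphans} rows reference unknown traits")
            for table, cols in (
                ("variant_ranks", "trait, variant_key"),
                ("gene_ranks", "trait, gene"),
            ):
                dups = conn.execute(
                    f"SELECT COUNT(*) FROM (SELECT {cols}, COUNT(*) c FROM {table} "
                    f"GROUP BY {cols} HAVING c > 1)"
                ).fetchone()[0]
                if dups:
                    problems.append(f"{table}: {dups} duplicate ({cols}) pairs")
            fk = conn.execute("PRAGMA foreign_key_check").fetchall()
            if fk:
                problems.append(f"foreign_key_check reported {len(fk)} violations")
        return problems
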