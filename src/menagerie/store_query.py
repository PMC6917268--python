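"""Embedded relational store for extracted facts, with conjunction queries.

One SQLite file holds a parent ``abstracts`` table and one child table per
multi-valued field (species, models, pairs, genes, interventions).  Queries
are conjunctions of field predicates with optional year and data-class
filters; results come back as matching PMIDs plus per-year counts and
proportions (denominator = all records passing the year/data-class filters
alone, so multi-valued rows need not sum to one).
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Sequence

QUERY_FIELDS = ("species", "model", "pair", "gene", "intervention",
                "outcome", "functional", "data_class")

_SCHEMA = """
CREATE TABLE IF NOT EXISTS abstracts (
    pmid TEXT PRIMARY KEY,
    year INTEGER NOT NULL,
    data_class TEXT NOT NULL CHECK (data_class IN ('primary', 'secondary')),
    outcome TEXT,
    functional TEXT
);
CREATE TABLE IF NOT EXISTS species (
    pmid TEXT NOT NULL REFERENCES abstracts(pmid) ON DELETE CASCADE,
    term TEXT NOT NULL, UNIQUE (pmid, term));
CREATE TABLE IF NOT EXISTS models (
    pmid TEXT NOT NULL REFERENCES abstracts(pmid) ON DELETE CASCADE,
    term TEXT NOT NULL, UNIQUE (pmid, term));
CREATE TABLE IF NOT EXISTS pairs (
    pmid TEXT NOT NULL REFERENCES abstracts(pmid) ON DELETE CASCADE,
    species TEXT NOT NULL, model TEXT NOT NULL,
    UNIQUE (pmid, species, model));
CREATE TABLE IF NOT EXISTS genes (
    pmid TEXT NOT NULL REFERENCES abstracts(pmid) ON DELETE CASCADE,
    canonical TEXT NOT NULL, identifier TEXT NOT NULL,
    UNIQUE (pmid, identifier));
CREATE TABLE IF NOT EXISTS interventions (
    pmid TEXT NOT NULL REFERENCES abstracts(pmid) ON DELETE CASCADE,
    canonical TEXT NOT NULL, identifier TEXT NOT NULL, source TEXT NOT NULL,
    UNIQUE (pmid, identifier));
"""


@dataclass
class FactRecord:
    """Consolidated per-PMID extraction record."""

    pmid: str
    year: int = 0
    data_class: str = "primary"
    species: set[str] = field(default_factory=set)
    models: set[str] = field(default_factory=set)
    pairs: set[tuple[str, str]] = field(default_factory=set)
    genes: set[tuple[str, str]] = field(default_factory=set)
    interventions: set[tuple[str, str, str]] = field(default_factory=set)
    outcome: str | None = None
    functional: str = "NO"

    def __post_init__(self):
        for sp, mo in self.pairs:
            if sp not in self.species or mo not in self.models:
                raise ValueError(
                    f"{self.pmid}: pair ({sp}, {mo}) not backed by species/models"
                )


@dataclass(frozen=True)
class Query:
    """Conjunction of (field, value) predicates with optional slice filters."""

    predicates: tuple[tuple[str, str], ...]
    years: tuple[int, ...] | None = None
    data_class: str | None = None

    def __post_init__(self):
        if not self.predicates:
            raise ValueError("query needs at least one predicate")
        for f, _ in self.predicates:
            if f not in QUERY_FIELDS:
                raise ValueError(f"unknown query field {f!r}")


def connect(path: str = ":memory:") -> sqlite3.Connection:
    db = sqlite3.connect(path)
    db.executescript(_SCHEMA)
    return db


def persist(facts: Iterable[FactRecord], db: sqlite3.Connection) -> int:
    """Idempotent upsert keyed by pmid; returns the number of records written."""
    n = 0
    with db:  # one transaction: a bad child rolls the record set back
        for r in facts:
            db.execute("DELETE FROM abstracts WHERE pmid = ?", (r.pmid,))
            for child in ("species", "models", "pairs", "genes", "interventions"):
                db.execute(f"DELETE FROM {child} WHERE pmid = ?", (r.pmid,))
            db.execute(
                "INSERT INTO abstracts VALUES (?, ?, ?, ?, ?)",
                (r.pmid, r.year, r.data_class, r.outcome, r.functional),
            )
            db.executemany(
                "INSERT INTO species VALUES (?, ?)",
                [(r.pmid, t) for t in sorted(r.species)],
            )
            db.executemany(
                "INSERT INTO models VALUES (?, ?)",
                [(r.pmid, t) for t in sorted(r.models)],
            )
            db.executemany(
                "INSERT INTO pairs VALUES (?, ?, ?)",
                [(r.pmid, s, m) for s, m in sorted(r.pairs)],
            )
            db.executemany(
                "INSERT INTO genes VALUES (?, ?, ?)",
                [(r.pmid, c, i) for c, i in sorted(r.genes)],
            )
            db.executemany(
                "INSERT INTO interventions VALUES (?, ?, ?, ?)",
                [(r.pmid, c, i, s) for c, i, s in sorted(r.interventions)],
            )
            n += 1
    return n


def read_all(db: sqlite3.Connection) -> list[FactRecord]:
    records = {}
    for pmid, year, dc, outcome, functional in db.execute(
        "SELECT pmid, year, data_class, outcome, functional FROM abstracts"
    ):
        records[pmid] = FactRecord(pmid, year, dc, outcome=outcome,
                                   functional=functional or "NO")
    for pmid, term in db.execute("SELECT pmid, term FROM species"):
        records[pmid].species.add(term)
    for pmid, term in db.execute("SELECT pmid, term FROM models"):
        records[pmid].models.add(term)
    for pmid, s, m in db.execute("SELECT pmid, species, model FROM pairs"):
        records[pmid].pairs.add((s, m))
    for pmid, c, i in db.execute("SELECT pmid, canonical, identifier FROM genes"):
        records[pmid].genes.add((c, i))
    for pmid, c, i, s in db.execute(
        "SELECT pmid, canonical, identifier, source FROM interventions"
    ):
        records[pmid].interventions.add((c, i, s))
    return sorted(records.values(), key=lambda r: r.pmid)


_PREDICATE_SQL = {
    "species": "pmid IN (SELECT pmid FROM species WHERE term = ?)",
    "model": "pmid IN (SELECT pmid FROM models WHERE term = ?)",
    "pair": "pmid IN (SELECT pmid FROM pairs WHERE species || '|' || model = ?)",
    "gene": "pmid IN (SELECT pmid FROM genes WHERE canonical = ? OR identifier = ?)",
    "intervention": ("pmid IN (SELECT pmid FROM interventions "
                     "WHERE canonical = ? OR identifier = ?)"),
    "outcome": "outcome = ?",
    "functional": "functional = ?",
    "data_class": "data_class = ?",
}


def _slice_clause(q: Query) -> tuple[str, list]:
    clauses, params = [], []
    if q.years is not None:
        clauses.append(f"year IN ({','.join('?' * len(q.years))})")
        params.extend(q.years)
    if q.data_class is not None:
        clauses.append("data_class = ?")
        params.append(q.data_class)
    return (" AND ".join(clauses) or "1=1"), params


def run_query(
    q: Query, db: sqlite3.Connection
) -> tuple[list[str], dict[int, int], dict[int, float]]:
    """PMIDs satisfying all predicates, plus per-year counts and proportions."""
    where, params = _slice_clause(q)
    for f, v in q.predicates:
        sql = _PREDICATE_SQL[f]
        where += f" AND {sql}"
        params.extend([v] * sql.count("?"))
    pmids = [r[0] for r in db.execute(
        f"SELECT pmid FROM abstracts WHERE {where} ORDER BY pmid", params
    )]
    counts = dict(db.execute(
        f"SELECT year, COUNT(*) FROM abstracts WHERE {where} GROUP BY year",
        params,
    ))
    base_where, base_params = _slice_clause(q)
    totals = dict(db.execute(
        f"SELECT year, COUNT(*) FROM abstracts WHERE {base_where} GROUP BY year",
        base_params,
    ))
    proportions = {
        y: (counts.get(y, 0) / totals[y] if totals.get(y) else 0.0)
        for y in totals
    }
    return pmids, counts, proportions


@dataclass
class Trend:
    counts: dict[int, int]
    fold_change: float | None  # None when the first-year count is zero

    @property
    def undefined(self) -> bool:
        return self.fold_change is None


def trend(
    entity_field: str,
    entity_value: str,
    years: Sequence[int],
    db: sqlite3.Connection,
    data_class: str | None = None,
) -> Trend:
    """Per-year counts for one entity and the last/first fold change."""
    if len(years) < 2:
        raise ValueError("trend needs at least two years")
    if entity_field not in QUERY_FIELDS:
        raise ValueError(f"unknown field {entity_field!r}")
    q = Query(((entity_field, entity_value),), tuple(years), data_class)
    _, counts, _ = run_query(q, db)
    counts = {y: counts.get(y, 0) for y in years}
    first, last = counts[years[0]], counts[years[-1]]
    return Trend(counts, (last / first) if first else None)


# --- in-memory reference aggregation (differential testing) -------------

def _record_matches(r: FactRecord, f: str, v: str) -> bool:
    if f == "species":
        return v in r.species
    if f == "model":
        return v in r.models
    if f == "pair":
        return any(f"{s}|{m}" == v for s, m in r.pairs)
    if f == "gene":
        return any(v in (c, i) for c, i in r.genes)
    if f == "intervention":
        return any(v in (c, i) for c, i, _ in r.interventions)
    if f == "outcome":
        return r.outcome == v
    if f == "functional":
        return r.functional == v
    if f == "data_class":
        return r.data_class == v
    raise ValueError(f"unknown field {f!r}")


def run_query_memory(
    q: Query, facts: Sequence[FactRecord]
) -> tuple[list[str], dict[int, int], dict[int, float]]:
    """Pure-Python aggregation equal, by contract, to :func:`run_query`."""
    in_slice = [
        r for r in facts
        if (q.years is None or r.year in q.years)
        and (q.data_class is None or r.data_class == q.data_class)
    ]
    hits = [
        r for r in in_slice
        if all(_record_matches(r, f, v) for f, v in q.predicates)
    ]
    counts: dict[int, int] = {}
    totals: dict[int, int] = {}
    for r in in_slice:
        totals[r.year] = totals.get(r.year, 0) + 1
    for r in hits:
        counts[r.year] = counts.get(r.year, 0) + 1
    proportions = {
        y: (counts.get(y, 0) / t if t else 0.0) for y, t in totals.items()
    }
    return sorted(r.pmid for r in hits), counts, proportions
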